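"""Reproducible simulation studies validating each pipeline stage.

Each function regenerates synthetic data under the package's standard study
conditions, runs the corresponding stage, and measures recovery of the
simulated truth. They power both the test suite and the repository's
acceptance script; all randomness derives from the single seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gwas import association_scan, detect_region, score_pool_matrix
from .haplotypes import (
    HaplotypeRegistry,
    clark_phase,
    diplotype_dosages,
    load_panel_fixture,
)
from .screen import rank_candidates
from .seromap import (
    Observation,
    anchor_map,
    concordance,
    cosegregation_extend,
)
from .simulate import (
    LineSpec,
    SimConfig,
    default_config,
    generate_dataset,
    line_profiles_from_truth,
    observe_serology,
    sample_population,
    simulate_pool_experiment,
    simulate_variant_table,
    stage_rng,
)

__all__ = [
    "pooled_gwas_recovery",
    "noiseless_r2",
    "type_one_error_rate",
    "candidate_screen_recovery",
    "phasing_recovery",
    "seromap_recovery",
]


def pooled_gwas_recovery(
    seed: int, n_replicates: int = 200, n_background: int = 2000
) -> dict:
    """Rank-recovery of the causal SNP from pooled intensities.

    Nine pools (three serology classes in each of three groups, pool sizes
    3-8), intensity noise sd 0.05, ``n_background`` null SNPs plus one causal
    SNP. Reports the fraction of replicates in which the causal SNP has the
    top r² and in which the delimited region contains the causal gene.
    """
    cfg = default_config(seed=seed)
    cfg.n_background_snps = n_background
    _, registry, _ = load_panel_fixture()
    positions = [m.position for m in registry.panel.markers]
    causal_pos = int(np.median(positions))
    _, genes = simulate_variant_table(cfg, registry)
    rng = stage_rng(seed, "pools")
    top1 = 0
    region_hits = 0
    for _ in range(n_replicates):
        exp = simulate_pool_experiment(cfg, rng=rng, causal_pos=causal_pos)
        scores = score_pool_matrix(
            exp.pools["expected_count"], exp.intensities
        )
        best = scores.loc[scores["r_squared"].idxmax(), "marker"]
        if best == exp.causal_marker:
            top1 += 1
        merged = scores.merge(exp.snp_meta, on="marker")
        region = detect_region(merged, 0.8, 1_000_000, genes=genes)
        if region is not None and cfg.causal_gene in region.genes:
            region_hits += 1
    return {
        "top1_rate": top1 / n_replicates,
        "region_rate": region_hits / n_replicates,
        "n_replicates": n_replicates,
    }


def noiseless_r2(seed: int) -> float:
    """r² of the causal SNP when intensities carry no noise at all."""
    cfg = default_config(seed=seed)
    cfg.intensity_noise_sd = 0.0
    cfg.pool_noise_sd = 0.0
    cfg.n_background_snps = 10
    exp = simulate_pool_experiment(cfg)
    scores = score_pool_matrix(exp.pools["expected_count"], exp.intensities)
    return float(
        scores.set_index("marker").loc[exp.causal_marker, "r_squared"]
    )


def type_one_error_rate(
    seed: int, n_samples: int = 50, n_markers: int = 1000, alpha: float = 0.05
) -> dict:
    """Empirical size of the trend test under a permuted (null) response."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    dosages = pd.DataFrame(
        rng.binomial(2, rng.uniform(0.1, 0.9, size=n_markers),
                     size=(n_samples, n_markers)).astype(float),
        columns=[f"m{j}" for j in range(n_markers)],
    )
    response = rng.permutation(
        np.repeat([0.0, 1.0, 2.0], [n_samples - 30, 20, 10])
    )
    hits, _ = association_scan(dosages, response)
    return {
        "rate": float((hits["p_value"] < alpha).mean()),
        "n_markers": int(len(hits)),
    }


def candidate_screen_recovery(n_seeds: int = 50, start_seed: int = 0) -> dict:
    """Fraction of seeds in which the screen returns exactly the causal gene."""
    _, registry, _ = load_panel_fixture()
    hits = 0
    for s in range(start_seed, start_seed + n_seeds):
        cfg = default_config(seed=s)
        variants, genes = simulate_variant_table(cfg, registry)
        _, _, hap2sero = load_panel_fixture()
        profiles = line_profiles_from_truth(cfg, hap2sero)
        candidates, _ = rank_candidates(genes, variants, profiles)
        if candidates == [cfg.causal_gene]:
            hits += 1
    return {"success_rate": hits / n_seeds, "n_seeds": n_seeds}


def phasing_recovery(seed: int, n_individuals_per_line: int = 52) -> dict:
    """De-novo Clark phasing of a population drawing all panel haplotypes.

    The default nine-line scenario plus two pedigree families gives roughly
    500 individuals. Phasing starts from homozygote-seeded discovery (no
    prior registry); resolutions are compared with the simulated truth as
    unordered pairs of allele vectors.
    """
    panel, fixture_registry, _ = load_panel_fixture()
    cfg = default_config(seed=seed, n_individuals=n_individuals_per_line)
    data = generate_dataset(cfg)
    discovery = HaplotypeRegistry(panel, prefix=panel.name)
    phases = clark_phase(data.genotypes, discovery)
    truth = {
        i.individual_id: tuple(
            sorted(
                fixture_registry.get(h).alleles for h in i.diplotype
            )
        )
        for i in data.individuals
    }
    n_resolved = 0
    n_correct = 0
    for p in phases:
        if not p.resolved:
            continue
        n_resolved += 1
        got = tuple(sorted(discovery.get(l).alleles for l in p.haplotypes))
        if got == truth[p.individual_id]:
            n_correct += 1
    return {
        "n_individuals": len(phases),
        "resolved_fraction": n_resolved / len(phases),
        "accuracy_of_resolved": n_correct / n_resolved if n_resolved else 0.0,
    }


def seromap_recovery(seed: int, het_error: float = 0.1, n: int = 10_000) -> dict:
    """Map recovery and concordance calibration with het-only serology error.

    One large three-allele segregating population plus two fixed anchor
    lines; the recovered haplotype -> allele map is compared entry-by-entry
    with the truth, and the audited agreement fraction with its closed-form
    expectation 1 - error * P(het).
    """
    _, registry, _ = load_panel_fixture()
    truth = {"CD99-H01": "D1", "CD99-H02": "D2", "CD99-H03": "D3"}
    cfg = SimConfig(
        seed=seed,
        lines=[
            LineSpec("FIX3", "WL", {"CD99-H03": 1.0}, "fixed"),
            LineSpec("FIX1", "WL", {"CD99-H01": 1.0}, "fixed"),
            LineSpec(
                "SEG", "WL",
                {"CD99-H01": 0.4, "CD99-H02": 0.3, "CD99-H03": 0.3},
                "segregating",
            ),
        ],
        n_individuals=n,
        serology_het_error=het_error,
    )
    pop = sample_population(cfg, registry)
    rng = stage_rng(seed, "serology")
    observations = [
        Observation(
            i.individual_id,
            i.diplotype,
            observe_serology(i, truth, het_error, rng),
        )
        for i in pop
    ]
    line_haps: dict[str, set] = {}
    for i in pop:
        line_haps.setdefault(i.line_id, set()).update(i.diplotype)
    profiles = line_profiles_from_truth(cfg, truth)
    anchors = anchor_map(profiles, line_haps)
    recovered, _ = cosegregation_extend(anchors, observations)
    map_correct = all(
        h in recovered and recovered.allele_of(h) == a for h, a in truth.items()
    )
    report = concordance(recovered, observations)
    p_het = float(
        np.mean([truth[i.diplotype[0]] != truth[i.diplotype[1]] for i in pop])
    )
    expected = 1.0 - het_error * p_het
    return {
        "map_correct": bool(map_correct),
        "agreement_fraction": report.fraction,
        "expected_agreement": expected,
        "p_het": p_het,
        "n_individuals": len(observations),
        "homozygote_misidentified": report.classes["homozygote_misidentified"],
        "classes": dict(report.classes),
    }
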