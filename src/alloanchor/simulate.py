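"""Synthetic populations, pools, intensities, serology and variant tables.

The generator emulates the data the identification pipeline consumes:
breeding lines fixed or segregating for panel haplotypes, two-generation
pedigree families, serology-defined DNA pools of 3-8 members, SNP-array
intensities linear in allele dosage with Gaussian noise, heterozygote-only
serology typing error, and an annotated variant table in which the causal
gene's missense variants track haplotype identity while decoy genes fail
either the membrane filter or the line-consistency screen by construction.

Randomness: one master seed; every stage draws from a generator seeded with
``SeedSequence([master_seed, offset])`` with fixed offsets — population 1,
mating 2, serology 3, pools 4, confirmation samples 6 — so stages are
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MappingError
from .haplotypes import HaplotypeRegistry, diplotype_dosages, load_panel_fixture
from .screen import LineProfile, classify_impact
from .seromap import SerologyRecord

__all__ = [
    "LineSpec",
    "SimConfig",
    "Individual",
    "default_config",
    "load_sim_config",
    "stage_rng",
    "sample_population",
    "mate",
    "observe_serology",
    "simulate_intensity",
    "pool_intensity",
    "simulate_pool_experiment",
    "simulate_variant_table",
    "population_genotypes",
    "line_profiles_from_truth",
    "generate_dataset",
    "SimDataset",
    "PoolExperiment",
]

_STAGE_OFFSETS = {
    "population": 1,
    "mating": 2,
    "serology": 3,
    "pools": 4,
    "variants": 5,
    "confirm": 6,
}

_POOL_SIZE_RANGE = (3, 8)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator derived from the master seed by fixed offset."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_OFFSETS[stage]]))


@dataclass
class LineSpec:
    """A breeding line: its haplotype frequencies and fixation status."""

    line_id: str
    breed: str
    haplotype_freqs: dict
    status: str  # "fixed" | "segregating"

    def validate(self, registry: HaplotypeRegistry) -> None:
        for label in self.haplotype_freqs:
            if label not in registry:
                raise ConfigurationError(
                    f"line {self.line_id}: unknown haplotype label {label!r}"
                )
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"line {self.line_id}: haplotype frequencies sum to {total}, not 1"
            )
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ConfigurationError(f"line {self.line_id}: negative frequency")
        if self.status not in {"fixed", "segregating"}:
            raise ConfigurationError(
                f"line {self.line_id}: bad status {self.status!r}"
            )
        positive = [l for l, f in self.haplotype_freqs.items() if f > 0]
        if self.status == "fixed" and len(positive) != 1:
            raise ConfigurationError(
                f"line {self.line_id}: fixed line must carry one haplotype"
            )


@dataclass
class SimConfig:
    """Full simulation scenario; defaults mirror the study's line structure."""

    seed: int = 0
    lines: list = field(default_factory=list)
    n_individuals: int = 55
    pool_sizes: tuple = (3, 8)
    intensity_noise_sd: float = 0.05
    pool_noise_sd: float = 0.02
    serology_het_error: float = 0.1
    n_background_snps: int = 2000
    causal_region: tuple = ("1", 129_700_000, 131_400_000)
    causal_gene: str = "CD99"
    decoy_genes: list = field(
        default_factory=lambda: [
            ("MEMDECOY1", True, False),   # membrane gene, pattern-free variants
            ("PATDECOY1", False, True),   # serology-tracking variants, cytoplasmic
        ]
    )
    n_families: int = 2
    n_progeny: int = 12
    pedigree_line: str = "WL4"

    def validate(self, registry: HaplotypeRegistry) -> None:
        if not self.lines:
            raise ConfigurationError("no lines configured")
        for spec in self.lines:
            spec.validate(registry)
        lo, hi = self.pool_sizes
        if not (_POOL_SIZE_RANGE[0] <= lo <= hi <= _POOL_SIZE_RANGE[1]):
            raise ConfigurationError("pool sizes must lie within [3, 8]")
        for name in ("intensity_noise_sd", "pool_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.serology_het_error <= 1.0:
            raise ConfigurationError("serology_het_error must lie in [0, 1]")
        if self.n_individuals < 1 or self.n_background_snps < 0:
            raise ConfigurationError("bad population / SNP counts")
        chrom, start, end = self.causal_region
        if start > end:
            raise ConfigurationError("causal region start > end")


def default_config(seed: int = 0, n_individuals: int = 55) -> SimConfig:
    """The demo scenario: nine lines mirroring the published line inventory
    (five White Leghorn elite lines, one inbred D1 line, Rhode Island Red and
    White Plymouth Rock lines without serology, and an unrelated typed
    group), all eleven panel haplotypes represented."""
    lines = [
        LineSpec("WL1", "WL", {"CD99-H02": 0.35, "CD99-H03": 0.65}, "segregating"),
        LineSpec("WL2", "WL", {"CD99-H03": 1.0}, "fixed"),
        LineSpec("WL3", "WL",
                 {"CD99-H01": 0.45, "CD99-H03": 0.50, "CD99-H06": 0.05},
                 "segregating"),
        LineSpec("WL4", "WL", {"CD99-H01": 0.5, "CD99-H03": 0.5}, "segregating"),
        LineSpec("WL5", "WL", {"CD99-H03": 1.0}, "fixed"),
        LineSpec("IAH7", "WL", {"CD99-H01": 1.0}, "fixed"),
        LineSpec("RIR1", "RIR",
                 {"CD99-H04": 0.5, "CD99-H07": 0.3, "CD99-H08": 0.2},
                 "segregating"),
        LineSpec("WPR1", "WPR",
                 {"CD99-H01": 0.3, "CD99-H04": 0.3, "CD99-H10": 0.2,
                  "CD99-H11": 0.2},
                 "segregating"),
        LineSpec("NIU", "WL",
                 {"CD99-H01": 0.3, "CD99-H02": 0.25, "CD99-H03": 0.25,
                  "CD99-H05": 0.1, "CD99-H09": 0.1},
                 "segregating"),
    ]
    return SimConfig(seed=seed, lines=lines, n_individuals=n_individuals)


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML file mirroring the dataclass fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    lines = [
        LineSpec(d["line_id"], d.get("breed", ""), dict(d["haplotype_freqs"]),
                 d["status"])
        for d in raw.pop("lines", [])
    ]
    region = raw.pop("causal_region", None)
    decoys = raw.pop("decoy_genes", None)
    cfg = SimConfig(lines=lines, **raw)
    if region is not None:
        cfg.causal_region = (str(region["chrom"]), int(region["start"]),
                             int(region["end"]))
    if decoys is not None:
        cfg.decoy_genes = [
            (d["gene_id"], bool(d["membrane"]), bool(d["tracks_serology"]))
            for d in decoys
        ]
    return cfg


@dataclass(frozen=True)
class Individual:
    individual_id: str
    line_id: str
    diplotype: tuple[str, str]
    sire_id: str | None = None
    dam_id: str | None = None


def sample_population(
    config: SimConfig, registry: HaplotypeRegistry
) -> list[Individual]:
    """Draw per-line diplotypes under Hardy-Weinberg from line frequencies."""
    config.validate(registry)
    rng = stage_rng(config.seed, "population")
    individuals: list[Individual] = []
    for spec in config.lines:
        labels = list(spec.haplotype_freqs)
        probs = np.array([spec.haplotype_freqs[l] for l in labels], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(labels), size=(config.n_individuals, 2), p=probs)
        for i, (a, b) in enumerate(draws):
            individuals.append(
                Individual(
                    f"{spec.line_id}_{i:04d}",
                    spec.line_id,
                    tuple(sorted((labels[a], labels[b]))),
                )
            )
    return individuals


def mate(
    sire: Individual,
    dam: Individual,
    n_progeny: int,
    rng: np.random.Generator | int,
) -> list[Individual]:
    """Mendelian progeny: one uniformly chosen haplotype from each parent."""
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    picks = rng.integers(0, 2, size=(n_progeny, 2))
    out = []
    for i, (a, b) in enumerate(picks):
        out.append(
            Individual(
                f"{sire.individual_id}x{dam.individual_id}_{i:03d}",
                sire.line_id,
                tuple(sorted((sire.diplotype[a], dam.diplotype[b]))),
                sire_id=sire.individual_id,
                dam_id=dam.individual_id,
            )
        )
    return out


def observe_serology(
    ind: Individual,
    hap2sero: Mapping[str, str],
    het_error: float,
    rng: np.random.Generator,
) -> SerologyRecord:
    """Serological typing with heterozygote-only error.

    Homozygotes are always reported correctly. A heterozygote is, with
    probability ``het_error``, reported with exactly one (uniformly chosen)
    true allele — the second either dropped (single-allele record) or
    replaced by the first (apparent homozygote); both alleles are never
    wrong.
    """
    try:
        a1, a2 = (hap2sero[h] for h in ind.diplotype)
    except KeyError as err:
        raise MappingError(
            f"{ind.individual_id}: haplotype {err.args[0]} has no serological "
            "assignment"
        ) from None
    if a1 == a2 or rng.random() >= het_error:
        return SerologyRecord(ind.individual_id, ind.line_id,
                              tuple(sorted((a1, a2))))
    kept = (a1, a2)[int(rng.integers(0, 2))]
    if rng.random() < 0.5:
        return SerologyRecord(ind.individual_id, ind.line_id, (kept,))
    return SerologyRecord(ind.individual_id, ind.line_id, (kept, kept))


def simulate_intensity(
    dosages: Sequence[float], noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """B-allele signal fraction: dosage/2 + Gaussian noise, truncated to [0,1].

    Missing dosages (NaN) yield missing intensities.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    d = np.asarray(dosages, dtype=float)
    out = np.clip(d / 2.0 + rng.normal(0.0, noise_sd, size=d.shape), 0.0, 1.0)
    out[np.isnan(d)] = np.nan
    return out


def pool_intensity(
    member_intensities: np.ndarray, pool_noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Pool signal: mean of member intensities plus additive Gaussian noise."""
    m = np.asarray(member_intensities, dtype=float)
    mean = np.nanmean(m, axis=0)
    return mean + rng.normal(0.0, pool_noise_sd, size=mean.shape)


@dataclass
class PoolExperiment:
    """A serology-defined pooling experiment ready for intensity regression."""

    pools: pd.DataFrame          # pool_id, expected_count, size
    intensities: pd.DataFrame    # pools x markers
    snp_meta: pd.DataFrame       # marker, chrom, pos
    causal_marker: str


def simulate_pool_experiment(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_groups: int = 3,
    causal_pos: int | None = None,
) -> PoolExperiment:
    """Simulate serology-defined DNA pools hybridised to a SNP array.

    Per group (two pedigree families plus one non-pedigree set by default),
    three pools are formed from individuals serologically typed as carrying
    0, 1 or 2 copies of the focal allele; every member of a pool shares that
    expected count. The causal SNP's member dosages equal the expected count;
    background SNPs draw member dosages binomially from a per-SNP allele
    frequency uniform on (0.1, 0.9), independent of pool class. Member
    intensities are dosage/2 plus Gaussian noise truncated to [0,1]; pool
    intensity is the member mean plus pool-level Gaussian noise.
    """
    if rng is None:
        rng = stage_rng(config.seed, "pools")
    chrom, start, end = config.causal_region
    n_bg = config.n_background_snps
    causal_marker = "causal_snp"
    markers = [causal_marker] + [f"bg{i:05d}" for i in range(n_bg)]
    if causal_pos is None:
        causal_pos = (start + end) // 2
    bg_pos = np.sort(rng.integers(1, 195_000_000, size=n_bg))
    meta = pd.DataFrame(
        {
            "marker": markers,
            "chrom": chrom,
            "pos": np.concatenate([[causal_pos], bg_pos]).astype(int),
        }
    )
    freqs = rng.uniform(0.1, 0.9, size=n_bg)
    lo, hi = config.pool_sizes
    pool_rows = []
    intens_rows = []
    for g in range(n_groups):
        for c in (0, 1, 2):
            size = int(rng.integers(lo, hi + 1))
            pool_id = f"G{g+1}_c{c}"
            pool_rows.append(
                {"pool_id": pool_id, "expected_count": c, "size": size}
            )
            causal_dosage = np.full((size, 1), float(c))
            bg_dosage = rng.binomial(2, freqs, size=(size, n_bg)).astype(float)
            dosages = np.hstack([causal_dosage, bg_dosage])
            member_int = np.clip(
                dosages / 2.0
                + rng.normal(0.0, config.intensity_noise_sd, size=dosages.shape),
                0.0,
                1.0,
            )
            intens_rows.append(
                pool_intensity(member_int, config.pool_noise_sd, rng)
            )
    pools = pd.DataFrame(pool_rows).set_index("pool_id")
    intensities = pd.DataFrame(
        np.vstack(intens_rows), index=pools.index, columns=markers
    )
    return PoolExperiment(pools, intensities, meta, causal_marker)


# ---------------------------------------------------------------------------
# variant table + gene annotation
# ---------------------------------------------------------------------------


def _line_call(alleles_present: set[int]) -> int:
    if alleles_present == {0}:
        return 0
    if alleles_present == {1}:
        return 2
    return 1


def _serology_pattern_columns(
    config: SimConfig, registry: HaplotypeRegistry
) -> tuple[list[dict], list[str]]:
    """Per-line genotype columns for variants tracking haplotype identity.

    One variant per panel marker that is polymorphic across the haplotypes
    present in the configured lines; each line's call reflects the alleles
    its haplotypes carry (both -> het), so fixed lines are homozygous and
    lines segregating at the marker show heterozygous calls.
    """
    panel = registry.panel
    line_haps = {
        spec.line_id: [l for l, f in spec.haplotype_freqs.items() if f > 0]
        for spec in config.lines
    }
    all_haps = sorted({h for hs in line_haps.values() for h in hs})
    bits = {h: panel.encode(registry.get(h).alleles) for h in all_haps}
    variants = []
    for k, marker in enumerate(panel.markers):
        present = {bits[h][k] for h in all_haps}
        if len(present) < 2:
            continue  # monomorphic in the simulated lines; never observed
        calls = {
            line: _line_call({bits[h][k] for h in haps})
            for line, haps in line_haps.items()
        }
        ref, alt = marker.ref_allele, marker.alt_allele
        if marker.variant_class == "indel":
            ref, alt = "CA", "C"  # sequence-level stand-in for a 1-bp deletion
        variants.append(
            {
                "variant_id": marker.assay_id,
                "pos": marker.position,
                "ref": ref,
                "alt": alt,
                "effect": marker.coding_effect,
                **calls,
            }
        )
    return variants, list(line_haps)


def simulate_variant_table(
    config: SimConfig, registry: HaplotypeRegistry
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct the annotated variant table and gene annotation set.

    The causal gene carries the panel's polymorphic variants with per-line
    genotypes derived from each line's haplotypes, so its missense variants
    correspond perfectly to haplotype identity. Membrane-flagged decoys carry
    missense variants whose calls cannot fit the line serology (fixed lines
    heterozygous at one variant, same-allele fixed lines differing at
    another, segregating lines invariant); non-membrane decoys duplicate the
    causal pattern but lack membrane annotation. Raises a configuration
    error when the region cannot hold all genes.
    """
    config.validate(registry)
    panel = registry.panel
    chrom, start, end = config.causal_region
    pattern_cols, line_ids = _serology_pattern_columns(config, registry)
    if not pattern_cols:
        raise ConfigurationError("configured lines are monomorphic over the panel")

    positions = [m.position for m in panel.markers]
    causal_span = (min(positions) - 500, max(positions) + 500)
    if not (start <= causal_span[0] and causal_span[1] <= end):
        raise ConfigurationError("causal gene span falls outside causal_region")

    genes = [
        {
            "gene_id": config.causal_gene,
            "chrom": chrom,
            "start": causal_span[0],
            "end": causal_span[1],
            "membrane": True,
            "components": "integral component of membrane;plasma membrane",
        }
    ]
    variant_rows = []
    for v in pattern_cols:
        variant_rows.append(
            {
                "chrom": chrom,
                "pos": v["pos"],
                "variant_id": v["variant_id"],
                "ref": v["ref"],
                "alt": v["alt"],
                "gene": config.causal_gene,
                "effect": v["effect"],
                "impact": classify_impact(v["effect"]),
                **{l: v[l] for l in line_ids},
            }
        )

    cursor = causal_span[1] + 50_000
    gene_width, gap = 20_000, 30_000
    fixed_lines = [s.line_id for s in config.lines if s.status == "fixed"]
    missense_pattern = [
        v for v in pattern_cols
        if classify_impact(v["effect"]) in {"HIGH", "MODERATE"}
    ]
    for gene_id, membrane, tracks in config.decoy_genes:
        gstart, gend = cursor, cursor + gene_width
        if gend > end:
            raise ConfigurationError(
                f"causal region too small to place decoy gene {gene_id}"
            )
        genes.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": gstart,
                "end": gend,
                "membrane": membrane,
                "components": (
                    "integral component of membrane" if membrane else "cytoplasm"
                ),
            }
        )
        if tracks:
            for i, v in enumerate(missense_pattern):
                variant_rows.append(
                    {
                        "chrom": chrom,
                        "pos": gstart + 2_000 * (i + 1),
                        "variant_id": f"{gene_id}_v{i+1}",
                        "ref": "G",
                        "alt": "A",
                        "gene": gene_id,
                        "effect": "missense",
                        "impact": "MODERATE",
                        **{l: v[l] for l in line_ids},
                    }
                )
        else:
            # v1: fixed lines heterozygous (breaks fixation); segregating
            # lines invariant (breaks segregation-present)
            variant_rows.append(
                {
                    "chrom": chrom,
                    "pos": gstart + 2_000,
                    "variant_id": f"{gene_id}_v1",
                    "ref": "G",
                    "alt": "A",
                    "gene": gene_id,
                    "effect": "missense",
                    "impact": "MODERATE",
                    **{l: (1 if l in fixed_lines else 0) for l in line_ids},
                }
            )
            # v2: same-allele fixed lines disagree when two or more exist
            variant_rows.append(
                {
                    "chrom": chrom,
                    "pos": gstart + 4_000,
                    "variant_id": f"{gene_id}_v2",
                    "ref": "G",
                    "alt": "A",
                    "gene": gene_id,
                    "effect": "missense",
                    "impact": "MODERATE",
                    **{
                        l: (2 if l == (fixed_lines[0] if fixed_lines else "") else 0)
                        for l in line_ids
                    },
                }
            )
        cursor = gend + gap
    variants = pd.DataFrame(variant_rows)
    genes_df = pd.DataFrame(genes)
    return variants, genes_df


# ---------------------------------------------------------------------------
# dataset assembly and file output
# ---------------------------------------------------------------------------


def population_genotypes(
    individuals: Sequence[Individual], registry: HaplotypeRegistry
) -> pd.DataFrame:
    """Panel genotype matrix (alt-allele dosages) implied by true diplotypes."""
    panel = registry.panel
    data = {
        ind.individual_id: diplotype_dosages(ind.diplotype, registry)
        for ind in individuals
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=panel.assay_ids
    ).astype(int)


def line_profiles_from_truth(
    config: SimConfig, hap2sero: Mapping[str, str]
) -> list[LineProfile]:
    """Serological line profiles implied by the true haplotype -> allele map.

    Lines carrying any unassigned haplotype are profiled as ``unknown`` (no
    serology available), mirroring untyped breeds.
    """
    profiles = []
    for spec in config.lines:
        haps = [l for l, f in spec.haplotype_freqs.items() if f > 0]
        if any(h not in hap2sero for h in haps):
            profiles.append(LineProfile(spec.line_id, spec.breed))
            continue
        alleles = frozenset(hap2sero[h] for h in haps)
        status = "fixed" if len(alleles) == 1 else "segregating"
        profiles.append(LineProfile(spec.line_id, spec.breed, alleles, status))
    return profiles


@dataclass
class SimDataset:
    """Everything one simulated study produces, plus the generating truth."""

    config: SimConfig
    individuals: list
    genotypes: pd.DataFrame
    serology: list
    pools: PoolExperiment
    variants: pd.DataFrame
    genes: pd.DataFrame
    line_ids: list
    profiles: list
    hap2sero: dict
    causal_gene: str


def generate_dataset(
    config: SimConfig, registry: HaplotypeRegistry | None = None
) -> SimDataset:
    """Run every simulation stage for one scenario.

    Pedigree families are added from the configured segregating line (both
    parents drawn from its haplotype pool); serology records are produced
    only for individuals whose haplotypes have serological assignments, as
    for real untyped breeds. The truth map ties the panel's haplotypes to
    their serological alleles.
    """
    if registry is None:
        _, registry, hap2sero = load_panel_fixture()
    else:
        _, _, hap2sero = load_panel_fixture()
    config.validate(registry)

    individuals = sample_population(config, registry)

    ped_line = [s for s in config.lines if s.line_id == config.pedigree_line]
    if config.n_families > 0 and ped_line:
        spec = ped_line[0]
        rng_mate = stage_rng(config.seed, "mating")
        labels = list(spec.haplotype_freqs)
        probs = np.array([spec.haplotype_freqs[l] for l in labels])
        probs = probs / probs.sum()
        for f in range(config.n_families):
            sire = Individual(
                f"{spec.line_id}_SIRE{f}", spec.line_id,
                tuple(sorted(labels[i] for i in
                             rng_mate.choice(len(labels), 2, p=probs))),
            )
            dam = Individual(
                f"{spec.line_id}_DAM{f}", spec.line_id,
                tuple(sorted(labels[i] for i in
                             rng_mate.choice(len(labels), 2, p=probs))),
            )
            individuals.extend([sire, dam])
            individuals.extend(mate(sire, dam, config.n_progeny, rng_mate))

    genotypes = population_genotypes(individuals, registry)

    rng_sero = stage_rng(config.seed, "serology")
    serology = [
        observe_serology(ind, hap2sero, config.serology_het_error, rng_sero)
        for ind in individuals
        if all(h in hap2sero for h in ind.diplotype)
    ]

    panel_positions = [m.position for m in registry.panel.markers]
    pools = simulate_pool_experiment(
        config, causal_pos=int(np.median(panel_positions))
    )
    variants, genes = simulate_variant_table(config, registry)
    line_ids = [s.line_id for s in config.lines]
    profiles = line_profiles_from_truth(config, hap2sero)
    return SimDataset(
        config=config,
        individuals=individuals,
        genotypes=genotypes,
        serology=serology,
        pools=pools,
        variants=variants,
        genes=genes,
        line_ids=line_ids,
        profiles=profiles,
        hap2sero=dict(hap2sero),
        causal_gene=config.causal_gene,
    )


# ---------------------------------------------------------------------------
# writers (plain-text formats)
# ---------------------------------------------------------------------------


def write_population(individuals: Sequence[Individual], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "line_id": i.line_id,
                "hap1": i.diplotype[0],
                "hap2": i.diplotype[1],
                "sire_id": i.sire_id or "",
                "dam_id": i.dam_id or "",
            }
            for i in individuals
        ]
    ).to_csv(path, index=False)


def write_serology(records: Sequence[SerologyRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "line_id": r.line_id,
                "alleles": ";".join(r.alleles),
                "partial": int(r.partial),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_pools(exp: PoolExperiment, pools_path, intensities_path) -> None:
    exp.pools.to_csv(pools_path)
    exp.intensities.to_csv(intensities_path, sep="\t")


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index_label="individual_id")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in genes.itertuples():
            components = getattr(r, "components", "")
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t"
                f"{int(bool(r.membrane))}\t{components}\n"
            )


def write_variants_vcf(
    variants: pd.DataFrame, line_ids: Sequence[str], path
) -> None:
    """Minimal VCF 4.2 with per-line genotype columns and GENE/EFFECT/IMPACT
    INFO keys; genotype codes 0/1/2 become 0/0, 0/1, 1/1 (missing ./.)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = sorted(set(variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,'
                 'Description="Coding effect">\n')
        fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,'
                 'Description="Predicted impact">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(line_ids) + "\n")
        for r in variants.sort_values(["chrom", "pos"]).itertuples():
            info = f"GENE={r.gene};EFFECT={r.effect};IMPACT={r.impact}"
            calls = "\t".join(
                gt.get(int(getattr(r, l)), "./.") for l in line_ids
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.variant_id}\t{r.ref}\t{r.alt}\t.\t"
                f"PASS\t{info}\tGT\t{calls}\n"
            )
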