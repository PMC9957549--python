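"""End-to-end orchestration: simulate -> gwas -> screen -> haplotype -> seromap.

One master configuration drives every stage; outputs are plain-text files
plus a JSON/text final report stating the candidate gene, the discovered
haplotype registry, the haplotype -> serological-allele map and the
concordance audit. A run manifest records the configuration snapshot, seeds,
per-stage wall time and a checksum for every written file. For a fixed seed
the report files are byte-identical across runs (timing lives only in the
manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import AlloanchorError
from .gwas import association_scan, detect_region, score_pool_matrix
from .haplotypes import (
    HaplotypeRegistry,
    clark_phase,
    haplotypes_from_homozygotes,
    load_panel_fixture,
)
from .screen import rank_candidates
from .seromap import Observation, anchor_map, concordance, cosegregation_extend
from .simulate import (
    SimConfig,
    generate_dataset,
    write_genes_bed,
    write_genotypes,
    write_pools,
    write_population,
    write_serology,
    write_variants_vcf,
)

__all__ = ["StageError", "run_all"]

logger = logging.getLogger(__name__)


class StageError(AlloanchorError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {err}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: SimConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["lines"] = [dataclasses.asdict(l) for l in config.lines]
    snap["pool_sizes"] = list(config.pool_sizes)
    snap["causal_region"] = list(config.causal_region)
    snap["decoy_genes"] = [list(d) for d in config.decoy_genes]
    return snap


def run_all(
    config: SimConfig,
    out_dir,
    r2_threshold: float = 0.8,
    max_gap_bp: int = 1_000_000,
    n_confirm: int = 50,
    confirm_line: str = "WL1",
    focal_allele: str = "D3",
) -> tuple[dict, dict]:
    """Execute the full identification pipeline on a simulated study.

    Returns ``(manifest, report)``; both are also written under ``out_dir``
    together with every intermediate file. The confirmation scan regresses
    the serology-derived focal-allele count of ``n_confirm`` individuals from
    ``confirm_line`` on their panel genotypes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    report: dict = {"version": __version__, "seed": config.seed}
    files: list[Path] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self_inner, exc_type, exc, tb):
                stage_times[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done (%.2fs)", name, stage_times[name])

        return _Timer()

    # -- simulate ---------------------------------------------------------
    with stage("simulate"):
        panel, fixture_registry, _ = load_panel_fixture()
        data = generate_dataset(config)
        write_population(data.individuals, out / "population.csv")
        write_genotypes(data.genotypes, out / "genotypes.csv")
        write_serology(data.serology, out / "serology.csv")
        write_pools(data.pools, out / "pools.csv", out / "intensities.tsv")
        write_variants_vcf(data.variants, data.line_ids, out / "variants.vcf")
        write_genes_bed(data.genes, out / "genes.bed")
        files += [out / f for f in
                  ("population.csv", "genotypes.csv", "serology.csv",
                   "pools.csv", "intensities.tsv", "variants.vcf", "genes.bed")]

    # -- pooled GWAS ------------------------------------------------------
    with stage("gwas"):
        scores = score_pool_matrix(
            data.pools.pools["expected_count"], data.pools.intensities
        ).merge(data.pools.snp_meta, on="marker")
        scores.to_csv(out / "pool_scores.tsv", sep="\t", index=False)
        files.append(out / "pool_scores.tsv")
        region = detect_region(
            scores, r2_threshold, max_gap_bp, genes=data.genes
        )
        report["region"] = region.to_dict() if region else None
        (out / "region.json").write_text(
            json.dumps(report["region"], indent=2, sort_keys=True) + "\n"
        )
        files.append(out / "region.json")

    # -- confirmation scan ------------------------------------------------
    with stage("confirm"):
        line_inds = [
            i for i in data.individuals if i.line_id == confirm_line
        ][:n_confirm]
        if len(line_inds) >= 3:
            ids = [i.individual_id for i in line_inds]
            response = [
                sum(data.hap2sero.get(h) == focal_allele for h in i.diplotype)
                for i in line_inds
            ]
            hits, skipped = association_scan(
                data.genotypes.loc[ids], response
            )
            hits.to_csv(out / "confirm_scan.tsv", sep="\t", index=False)
            files.append(out / "confirm_scan.tsv")
            top = (
                hits.sort_values("p_value").iloc[0].to_dict()
                if not hits.empty else None
            )
            report["confirm_top_marker"] = top
        else:
            report["confirm_top_marker"] = None

    # -- candidate screen -------------------------------------------------
    with stage("screen"):
        candidates, audit = rank_candidates(
            data.genes, data.variants, data.profiles
        )
        audit.to_csv(out / "screen_report.tsv", sep="\t", index=False)
        files.append(out / "screen_report.tsv")
        report["candidate_genes"] = candidates

    # -- haplotyping ------------------------------------------------------
    with stage("haplotype"):
        discovery = HaplotypeRegistry(panel, prefix=panel.name)
        for vec in haplotypes_from_homozygotes(data.genotypes, panel):
            discovery.register([vec])
        phases = clark_phase(data.genotypes, discovery)
        n_resolved = sum(p.resolved for p in phases)
        report["haplotyping"] = {
            "n_individuals": len(phases),
            "n_resolved": n_resolved,
            "n_haplotypes": len(discovery),
            "registry": {
                lbl: list(discovery.get(lbl).alleles) for lbl in discovery.labels
            },
        }
        discovery.to_frame().to_csv(out / "registry.csv", index=False)
        files.append(out / "registry.csv")

    # -- serology mapping -------------------------------------------------
    with stage("seromap"):
        phase_by_id = {p.individual_id: p for p in phases}
        line_of = {i.individual_id: i.line_id for i in data.individuals}
        line_haps: dict[str, set] = {}
        for p in phases:
            if p.resolved:
                line_haps.setdefault(line_of[p.individual_id], set()).update(
                    p.haplotypes
                )
        anchors = anchor_map(data.profiles, line_haps)
        observations = []
        for rec in data.serology:
            p = phase_by_id.get(rec.individual_id)
            if p is not None and p.resolved:
                observations.append(
                    Observation(rec.individual_id, p.haplotypes, rec)
                )
        extended, ext_report = cosegregation_extend(
            anchors, observations, discovery
        )
        audit_report = concordance(extended, observations)
        map_df = pd.DataFrame(extended.to_rows())
        map_df.to_csv(out / "serology_map.csv", index=False)
        files.append(out / "serology_map.csv")
        report["serology_map"] = extended.to_rows()
        report["serology_extension"] = ext_report
        report["concordance"] = audit_report.to_dict()

    # -- report + manifest ------------------------------------------------
    report_json = json.dumps(report, indent=2, sort_keys=True) + "\n"
    (out / "report.json").write_text(report_json)
    (out / "report.txt").write_text(_render_text_report(report))
    files += [out / "report.json", out / "report.txt"]

    manifest = {
        "version": __version__,
        "config": _config_snapshot(config),
        "seed": config.seed,
        "stages": list(stage_times),
        "stage_wall_time_s": stage_times,
        "files": {str(f.name): _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest, report


def _render_text_report(report: dict) -> str:
    lines = ["alloanchor pipeline report", "=" * 26, ""]
    region = report.get("region")
    if region:
        lines.append(
            f"Association peak: chr{region['chrom']}:"
            f"{region['start']}-{region['end']} "
            f"({len(region['markers'])} marker(s); peak {region['peak_marker']}, "
            f"score {region['peak_score']:.4f})"
        )
        if region["genes"]:
            lines.append(f"Genes in region: {', '.join(region['genes'])}")
    else:
        lines.append("Association peak: none detected")
    cands = report.get("candidate_genes", [])
    lines.append(f"Candidate gene(s): {', '.join(cands) if cands else 'none'}")
    hap = report.get("haplotyping", {})
    if hap:
        lines.append(
            f"Haplotyping: {hap['n_resolved']}/{hap['n_individuals']} individuals "
            f"resolved; {hap['n_haplotypes']} haplotypes"
        )
    for entry in report.get("serology_map", []):
        lines.append(
            f"  {entry['haplotype']} -> {entry['allele']} ({entry['provenance']})"
        )
    conc = report.get("concordance")
    if conc:
        lines.append(
            f"Concordance: {conc['n_agree']}/{conc['n_total']} "
            f"({100 * conc['fraction']:.1f}%) agree; "
            f"discordance classes: {conc['classes']}"
        )
    return "\n".join(lines) + "\n"
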