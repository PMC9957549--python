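"""Candidate-gene reduction: variant impact, membrane annotation, line consistency.

Given a delimited candidate region, the screen keeps genes that (1) encode
proteins annotated to cell-surface membranes and (2) carry HIGH/MODERATE
impact variants whose per-line genotypes fit the serological knowledge of the
breeding lines: lines fixed for the same allele must be homozygous and
identical, lines fixed for different alleles must differ somewhere, and lines
known to segregate must actually show segregation.

Impact classification is a rule-based mapping from sequence-ontology coding
effects to the conventional four-level impact vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, FormatError

__all__ = [
    "IMPACT_BY_EFFECT",
    "DEFAULT_MEMBRANE_TERMS",
    "LineProfile",
    "ConsistencyVerdict",
    "classify_impact",
    "select_impactful",
    "membrane_filter",
    "consistency_check",
    "rank_candidates",
    "read_vcf",
    "read_gene_bed",
    "read_line_profiles",
]

logger = logging.getLogger(__name__)

IMPACT_BY_EFFECT = {
    "missense": "MODERATE",
    "stop_gained": "HIGH",
    "frameshift": "HIGH",
    "splice_region": "LOW",
    "synonymous": "LOW",
    "intronic": "MODIFIER",
    "intergenic": "MODIFIER",
}

IMPACTFUL = frozenset({"HIGH", "MODERATE"})

DEFAULT_MEMBRANE_TERMS = frozenset(
    {"plasma membrane", "integral component of membrane", "cell surface"}
)

# genotype codes in per-line columns of a variant table
_MISSING = -1


def classify_impact(coding_effect: str) -> str:
    """Map a sequence-ontology coding effect to HIGH/MODERATE/LOW/MODIFIER."""
    try:
        return IMPACT_BY_EFFECT[coding_effect]
    except KeyError:
        raise AnnotationError(
            f"unknown coding effect {coding_effect!r}; expected one of "
            f"{sorted(IMPACT_BY_EFFECT)}"
        ) from None


def select_impactful(variants: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the variants with HIGH or MODERATE impact.

    If the table carries an ``effect`` column but no ``impact`` column, the
    impacts are derived first via :func:`classify_impact`.
    """
    if variants.empty:
        return variants.copy()
    v = variants.copy()
    if "impact" not in v.columns:
        if "effect" not in v.columns:
            raise FormatError("variant table needs an 'impact' or 'effect' column")
        v["impact"] = v["effect"].map(classify_impact)
    return v[v["impact"].isin(IMPACTFUL)]


def membrane_filter(
    genes: pd.DataFrame, membrane_terms: Iterable[str] = DEFAULT_MEMBRANE_TERMS
) -> pd.DataFrame:
    """Genes whose cellular-component terms intersect the membrane-term set.

    ``genes`` needs a ``components`` column with semicolon-joined GO
    cellular-component terms; genes with an empty component set are excluded.
    """
    terms = {t.strip().lower() for t in membrane_terms}

    def is_membrane(components) -> bool:
        if not isinstance(components, str) or not components.strip():
            return False
        gene_terms = {t.strip().lower() for t in components.split(";") if t.strip()}
        return bool(gene_terms & terms)

    return genes[genes["components"].map(is_membrane)]


@dataclass(frozen=True)
class LineProfile:
    """A breeding line's serological knowledge: its known alleles and whether
    it is fixed for one allele, segregating for several, or untyped."""

    line_id: str
    breed: str = ""
    known_alleles: frozenset = frozenset()
    status: str = "unknown"

    def __post_init__(self) -> None:
        if self.status not in {"fixed", "segregating", "unknown"}:
            raise FormatError(f"{self.line_id}: bad status {self.status!r}")
        if self.status == "fixed" and len(self.known_alleles) != 1:
            raise FormatError(
                f"{self.line_id}: a fixed line must have exactly one known allele"
            )


@dataclass
class ConsistencyVerdict:
    """Outcome of the four line-consistency checks for one gene.

    checks:
      same_allele_identity     fixed lines sharing an allele are homozygous
                               and identical over impactful variants
      cross_allele_difference  fixed lines with different alleles differ at
                               at least one impactful variant
      segregation_present      every segregating line shows a het call or
                               both homozygous classes across the gene
      fixation_respected       fixed lines carry no het call
    """

    gene_id: str
    checks: dict = field(default_factory=dict)
    passed: bool = False
    n_impactful: int = 0
    n_missing_ignored: int = 0
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "checks": dict(self.checks),
            "passed": bool(self.passed),
            "n_impactful": int(self.n_impactful),
            "n_missing_ignored": int(self.n_missing_ignored),
            "reason": self.reason,
        }


def _line_matrix(variants: pd.DataFrame, line_ids: Sequence[str]) -> np.ndarray:
    missing_cols = [l for l in line_ids if l not in variants.columns]
    if missing_cols:
        raise FormatError(f"variant table lacks line columns: {missing_cols}")
    M = variants[list(line_ids)].to_numpy(dtype=float)
    M = np.where(np.isnan(M), _MISSING, M).astype(int)
    bad = ~np.isin(M, [_MISSING, 0, 1, 2])
    if bad.any():
        raise FormatError("line genotype codes must be 0/1/2 or missing")
    return M


def consistency_check(
    gene_id: str,
    variants: pd.DataFrame,
    profiles: Sequence[LineProfile],
) -> ConsistencyVerdict:
    """Check one gene's impactful variants against line-level serology.

    Only HIGH/MODERATE variants of ``gene_id`` enter the checks; missing
    genotype calls are ignored per check, with the ignored count logged and
    recorded on the verdict. Lines with status ``unknown`` contribute to no
    check. With no impactful variant the verdict fails outright with reason
    ``no-impactful-variants``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two line profiles")
    gene_vars = variants[variants["gene"] == gene_id]
    imp = select_impactful(gene_vars)
    verdict = ConsistencyVerdict(gene_id=gene_id, n_impactful=len(imp))
    if imp.empty:
        verdict.reason = "no-impactful-variants"
        verdict.checks = {
            "same_allele_identity": False,
            "cross_allele_difference": False,
            "segregation_present": False,
            "fixation_respected": False,
        }
        return verdict

    line_ids = [p.line_id for p in profiles]
    M = _line_matrix(imp, line_ids)  # variants x lines
    col = {l: j for j, l in enumerate(line_ids)}
    n_missing = int((M == _MISSING).sum())
    if n_missing:
        logger.info("%s: ignoring %d missing calls in consistency checks",
                    gene_id, n_missing)
    verdict.n_missing_ignored = n_missing

    fixed = [p for p in profiles if p.status == "fixed"]
    segregating = [p for p in profiles if p.status == "segregating"]

    # (a) fixed lines sharing an allele: homozygous, identical where observed
    same_ok = True
    by_allele: dict[str, list[LineProfile]] = {}
    for p in fixed:
        by_allele.setdefault(next(iter(p.known_alleles)), []).append(p)
    for allele, group in by_allele.items():
        for p in group:
            g = M[:, col[p.line_id]]
            if np.any(g == 1):
                same_ok = False
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a = M[:, col[group[i].line_id]]
                b = M[:, col[group[j].line_id]]
                both = (a != _MISSING) & (b != _MISSING)
                if np.any(a[both] != b[both]):
                    same_ok = False

    # (b) fixed lines with different alleles differ at >=1 observed variant
    cross_ok = True
    alleles = list(by_allele)
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            for p in by_allele[alleles[i]]:
                for q in by_allele[alleles[j]]:
                    a = M[:, col[p.line_id]]
                    b = M[:, col[q.line_id]]
                    both = (a != _MISSING) & (b != _MISSING)
                    if not np.any(a[both] != b[both]):
                        cross_ok = False

    # (c) segregating lines show segregation somewhere in the gene
    seg_ok = True
    for p in segregating:
        g = M[:, col[p.line_id]]
        obs = g[g != _MISSING]
        if not (np.any(obs == 1) or (np.any(obs == 0) and np.any(obs == 2))):
            seg_ok = False

    # (d) fixed lines carry no het call
    fix_ok = all(
        not np.any(M[:, col[p.line_id]] == 1) for p in fixed
    )

    verdict.checks = {
        "same_allele_identity": same_ok,
        "cross_allele_difference": cross_ok,
        "segregation_present": seg_ok,
        "fixation_respected": fix_ok,
    }
    verdict.passed = all(verdict.checks.values())
    return verdict


def rank_candidates(
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    profiles: Sequence[LineProfile],
    membrane_terms: Iterable[str] = DEFAULT_MEMBRANE_TERMS,
) -> tuple[list[str], pd.DataFrame]:
    """Reduce region genes to candidates and report every gene's verdict.

    Candidates are the membrane-annotated genes passing all four consistency
    checks, ordered by the number of impactful variants supporting the
    pattern (descending), ties by gene id. The report table lists every gene
    in the input with its membrane flag, per-check booleans, pass flag and
    support count; an empty candidate list is a valid outcome, returned with
    the full audit.
    """
    membrane_ids = set(membrane_filter(genes, membrane_terms)["gene_id"])
    rows = []
    for gene_id in genes["gene_id"]:
        verdict = consistency_check(gene_id, variants, profiles)
        rows.append(
            {
                "gene_id": gene_id,
                "membrane": gene_id in membrane_ids,
                **verdict.checks,
                "passed": verdict.passed,
                "n_impactful": verdict.n_impactful,
                "reason": verdict.reason,
                "candidate": bool(verdict.passed and gene_id in membrane_ids),
            }
        )
    report = pd.DataFrame(rows)
    ranked = report[report["candidate"]].sort_values(
        ["n_impactful", "gene_id"], ascending=[False, True]
    )
    return list(ranked["gene_id"]), report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> tuple[pd.DataFrame, list[str]]:
    """Read a variant table with per-line genotype columns from a VCF.

    Expects INFO keys ``GENE`` and ``EFFECT`` (or ``IMPACT``); sample columns
    are breeding lines. Genotypes map to 0 (hom-ref), 1 (het), 2 (hom-alt)
    and missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = {0: 0, 1: 1, 2: _MISSING, 3: 2}
    rows = []
    for v in vcf:
        rec = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
            "ref": v.REF,
            "alt": v.ALT[0] if v.ALT else ".",
            "gene": v.INFO.get("GENE"),
        }
        effect = v.INFO.get("EFFECT")
        impact = v.INFO.get("IMPACT")
        if effect is not None:
            rec["effect"] = effect
        rec["impact"] = impact if impact is not None else classify_impact(effect)
        for line, gt in zip(lines, v.gt_types):
            rec[line] = code[int(gt)]
        rows.append(rec)
    vcf.close()
    df = pd.DataFrame(rows)
    if not df.empty:
        df[lines] = df[lines].astype(int)
    return df, lines


def read_gene_bed(path) -> pd.DataFrame:
    """Gene annotation from a BED-like file: chrom, start0, end, gene_id,
    membrane flag (0/1), semicolon-joined component terms. Returns 1-based
    inclusive spans."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start0", "end", "gene_id", "membrane", "components"],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["start0"].astype(int) + 1,
            "end": df["end"].astype(int),
            "membrane": df["membrane"].astype(int).astype(bool),
            "components": df["components"].fillna(""),
        }
    )
    return out


def read_line_profiles(path) -> list[LineProfile]:
    """Line profiles from CSV: line_id, breed, known_alleles (;-joined), status."""
    df = pd.read_csv(path, dtype=str)
    profiles = []
    for r in df.itertuples():
        alleles = frozenset(
            a for a in str(r.known_alleles).split(";") if a and a != "nan"
        )
        profiles.append(
            LineProfile(r.line_id, getattr(r, "breed", ""), alleles, r.status)
        )
    return profiles
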