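"""Pooled-intensity GWAS scoring, confirmation scan, and region delimiting.

The pooled analysis scores each array SNP by ordinary least squares of the
serology-implied expected B-allele count of each DNA pool (response) on the
pool's array intensity at that SNP (explanatory); the coefficient of
determination r² — the squared Pearson correlation — measures how faithfully
the SNP's intensity tracks the serological classification of the pools.

The confirmation scan works on individually genotyped samples: a linear trend
regression of the serology-derived focal-allele count on the 0/1/2 allele
dosage at each marker, with a two-sided F test.

Genotype calls are recoded as 0 for AA, 1 for AB and 2 for BB (copies of the
B allele); quality control retains markers with minor allele frequency >= 0.1
and missing fraction <= 0.1 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, FormatError

__all__ = [
    "CALL_DOSAGE",
    "QcParams",
    "PoolObservation",
    "SnpScore",
    "GwasHit",
    "Region",
    "recode_calls",
    "qc_filter",
    "score_snp_regression",
    "score_pool_matrix",
    "association_scan",
    "detect_region",
    "manhattan_plot",
]

logger = logging.getLogger(__name__)

CALL_DOSAGE = {"AA": 0.0, "AB": 1.0, "BB": 2.0}
_MISSING_CALLS = {"missing", "NA", "", "./.", "--"}

_TINY_P = float(np.finfo(np.float64).tiny)  # smallest positive normal double


def recode_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Recode AA/AB/BB calls to B-allele dosages 0/1/2; missing stays missing.

    Raises :class:`FormatError` naming the first offending row and column on
    any symbol outside the four-symbol alphabet.
    """
    out = pd.DataFrame(
        np.nan, index=calls.index, columns=calls.columns, dtype=float
    )
    for col in calls.columns:
        vals = calls[col]
        for idx, v in vals.items():
            if pd.isna(v) or v in _MISSING_CALLS:
                continue
            try:
                out.at[idx, col] = CALL_DOSAGE[v]
            except KeyError:
                raise FormatError(
                    f"unknown genotype symbol {v!r} at row {idx!r}, column {col!r}"
                ) from None
    return out


@dataclass(frozen=True)
class QcParams:
    """Marker quality-control thresholds.

    ``maf_min`` is the minimum minor-allele frequency (computed from B-allele
    dosages over non-missing calls); ``missing_max`` the maximum tolerated
    missing-call fraction.
    """

    maf_min: float = 0.1
    missing_max: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not 0.0 <= self.missing_max <= 1.0:
            raise ValueError("missing_max must lie in [0, 1]")


def qc_filter(
    dosages: pd.DataFrame, params: QcParams = QcParams()
) -> tuple[list[str], pd.DataFrame]:
    """Apply MAF / missingness filters to a samples x markers dosage matrix.

    Returns the retained marker list and an audit table with one row per
    marker (maf, missing fraction, retained flag, comma-joined removal
    reasons drawn from {"maf", "missing"}).
    """
    if dosages.shape[0] == 0 or dosages.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    X = dosages.to_numpy(dtype=float)
    miss = np.isnan(X)
    n_obs = (~miss).sum(axis=0)
    miss_frac = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nansum(X, axis=0) / (2.0 * n_obs)
    maf = np.minimum(f, 1.0 - f)
    rows = []
    retained = []
    for j, marker in enumerate(dosages.columns):
        reasons = []
        if n_obs[j] == 0 or maf[j] < params.maf_min:
            reasons.append("maf")
        if miss_frac[j] > params.missing_max:
            reasons.append("missing")
        if n_obs[j] == 0:
            # undefined MAF: missingness is the substantive reason
            reasons = ["missing"]
        keep = not reasons
        if keep:
            retained.append(marker)
        rows.append(
            {
                "marker": marker,
                "maf": maf[j] if n_obs[j] else np.nan,
                "missing_frac": miss_frac[j],
                "retained": keep,
                "reason": ",".join(reasons),
            }
        )
    return retained, pd.DataFrame(rows)


@dataclass(frozen=True)
class PoolObservation:
    """One DNA pool: its serology-implied expected B-allele count (0, 1 or 2
    at the focal locus) and its per-marker array intensities."""

    pool_id: str
    expected_count: int
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.expected_count not in (0, 1, 2):
            raise ValueError("expected_count must be 0, 1 or 2")


@dataclass(frozen=True)
class SnpScore:
    marker_id: str
    r_squared: float
    n_obs: int
    degenerate: bool
    slope: float = float("nan")
    intercept: float = float("nan")


def _r2_stats(y: np.ndarray, x: np.ndarray) -> tuple[float, int, bool, float, float]:
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3:
        return 0.0, n, True, np.nan, np.nan
    vx = x - x.mean()
    vy = y - y.mean()
    sxx = float(vx @ vx)
    syy = float(vy @ vy)
    if sxx == 0.0 or syy == 0.0:
        return 0.0, n, True, np.nan, np.nan
    sxy = float(vx @ vy)
    r2 = (sxy * sxy) / (sxx * syy)
    slope = sxy / sxx
    return r2, n, False, slope, float(y.mean() - slope * x.mean())


def score_snp_regression(
    observations: Sequence[PoolObservation], marker_id: str
) -> SnpScore:
    """Score one SNP by OLS of expected pool allele count on pool intensity.

    Pools whose intensity at the marker is missing are dropped. With fewer
    than three usable pools, or zero variance in either variable, the score
    is emitted with ``r_squared = 0`` and the degenerate flag set.
    """
    y = np.array([o.expected_count for o in observations], dtype=float)
    x = np.array(
        [o.intensities.get(marker_id, np.nan) for o in observations], dtype=float
    )
    r2, n, degen, slope, intercept = _r2_stats(y, x)
    return SnpScore(marker_id, r2, n, degen, slope, intercept)


def score_pool_matrix(
    expected_counts: pd.Series, intensities: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised per-marker r² over a pools x markers intensity matrix.

    ``expected_counts`` is indexed by pool id and aligned against the
    intensity matrix rows. Returns a table (marker, r_squared, n_obs,
    degenerate) in marker order; identical marker-by-marker to
    :func:`score_snp_regression`.
    """
    y = expected_counts.reindex(intensities.index).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise AnalysisError("expected counts missing for some pools")
    X = intensities.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    n = mask.sum(axis=0)
    Xz = np.where(mask, X, 0.0)
    sx = Xz.sum(axis=0)
    sxx = (Xz * Xz).sum(axis=0)
    sy = y @ mask
    syy = (y * y) @ mask
    sxy = y @ Xz
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r2 = np.where(
            (varx > 0) & (vary > 0), cov * cov / (varx * vary), 0.0
        )
    degenerate = (n < 3) | (varx <= 0) | (vary <= 0)
    r2 = np.where(degenerate, 0.0, r2)
    return pd.DataFrame(
        {
            "marker": intensities.columns,
            "r_squared": r2,
            "n_obs": n,
            "degenerate": degenerate,
        }
    )


@dataclass(frozen=True)
class GwasHit:
    marker_id: str
    statistic: float
    p_value: float
    slope: float = float("nan")


def association_scan(
    dosages: pd.DataFrame, response: Sequence[float]
) -> tuple[pd.DataFrame, list[str]]:
    """Linear trend regression of a per-sample allele count on marker dosage.

    Per marker, OLS of response on 0/1/2 dosage with a two-sided F test
    (1, n-2 df). Markers with zero dosage variance are skipped with a logged
    notice and returned in the skip list. Underflowing p-values are reported
    as the smallest positive normal double rather than zero.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != dosages.shape[0]:
        raise ValueError("response length does not match sample count")
    if np.nanstd(y) == 0:
        raise AnalysisError("response is constant; trend test undefined")
    rows = []
    skipped: list[str] = []
    X = dosages.to_numpy(dtype=float)
    for j, marker in enumerate(dosages.columns):
        x = X[:, j]
        mask = ~(np.isnan(x) | np.isnan(y))
        xs, ys = x[mask], y[mask]
        n = mask.sum()
        if n < 3 or np.all(xs == xs[0]):
            skipped.append(marker)
            logger.info("association_scan: skipping %s (no dosage variance)", marker)
            continue
        r2, n, degen, slope, _ = _r2_stats(ys, xs)
        if degen:
            skipped.append(marker)
            logger.info("association_scan: skipping %s (degenerate)", marker)
            continue
        if r2 >= 1.0:
            fstat, p = np.inf, _TINY_P
        else:
            fstat = r2 / (1.0 - r2) * (n - 2)
            p = float(stats.f.sf(fstat, 1, n - 2))
            p = max(p, _TINY_P)
        rows.append(
            {"marker": marker, "statistic": fstat, "p_value": p, "slope": slope,
             "n_obs": n}
        )
    return pd.DataFrame(rows), skipped


@dataclass
class Region:
    """A 1-based inclusive genomic interval with its member markers."""

    chrom: str
    start: int
    end: int
    markers: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    peak_marker: str | None = None
    peak_score: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": int(self.start),
            "end": int(self.end),
            "markers": list(self.markers),
            "genes": list(self.genes),
            "peak_marker": self.peak_marker,
            "peak_score": None if np.isnan(self.peak_score) else float(self.peak_score),
        }


def detect_region(
    scores: pd.DataFrame,
    threshold: float,
    max_gap_bp: int,
    score_col: str = "r_squared",
    higher_is_better: bool = True,
    genes: pd.DataFrame | None = None,
) -> Region | None:
    """Delimit the association peak as the smallest interval covering the
    maximal run of passing markers.

    ``scores`` needs columns ``marker``, ``chrom``, ``pos`` and the score
    column. A marker passes when its score is >= ``threshold`` (or <= for
    p-value-like scores with ``higher_is_better=False``). Passing markers on
    one chromosome belong to the same run while consecutive passing positions
    are at most ``max_gap_bp`` apart. The longest run wins; ties are broken
    by the higher peak score, then by the leftmost start. Returns ``None``
    when no marker passes.

    If a gene table (gene_id, chrom, start, end) is supplied, genes
    overlapping the interval are attached.
    """
    req = {"marker", "chrom", "pos", score_col}
    if not req.issubset(scores.columns):
        raise FormatError(f"score table needs columns {sorted(req)}")
    s = scores[score_col].to_numpy(dtype=float)
    passing = scores[(s >= threshold) if higher_is_better else (s <= threshold)]
    if passing.empty:
        return None
    runs: list[Region] = []
    for chrom, grp in passing.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            block = grp.iloc[a : b + 1]
            sc = block[score_col].to_numpy(dtype=float)
            peak_i = int(np.argmax(sc) if higher_is_better else np.argmin(sc))
            runs.append(
                Region(
                    chrom=str(chrom),
                    start=int(block["pos"].iloc[0]),
                    end=int(block["pos"].iloc[-1]),
                    markers=list(block["marker"]),
                    peak_marker=str(block["marker"].iloc[peak_i]),
                    peak_score=float(sc[peak_i]),
                )
            )

    def sort_key(r: Region):
        peak = r.peak_score if higher_is_better else -r.peak_score
        return (len(r.markers), peak, -r.start)

    best = max(runs, key=sort_key)
    if genes is not None:
        hit = genes[
            (genes["chrom"].astype(str) == best.chrom)
            & (genes["end"].astype(int) >= best.start)
            & (genes["start"].astype(int) <= best.end)
        ]
        best.genes = list(hit["gene_id"])
    return best


def manhattan_plot(scores: pd.DataFrame, path, score_col: str = "r_squared"):
    """Write a simple per-chromosome scatter of marker scores to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, (chrom, grp) in enumerate(scores.groupby("chrom", sort=True)):
        grp = grp.sort_values("pos")
        ax.scatter(grp["pos"] + offset, grp[score_col], s=4,
                   color="C0" if i % 2 == 0 else "C1", label=None)
        offset += int(grp["pos"].max()) + 1
    ax.set_xlabel("genome position (concatenated)")
    ax.set_ylabel(score_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
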