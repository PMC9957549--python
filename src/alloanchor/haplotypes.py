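"""Multi-marker haplotype definitions, registries, and Clark-style phasing.

A *panel* is an ordered set of biallelic assays (SNPs and indels) inside one
candidate gene; a *haplotype* is an ordered allele vector over that panel.
The package ships the 8-marker CD99 panel and the 11 haplotypes observed in
White Leghorn, Rhode Island Red and White Plymouth Rock layer lines, loadable
with :func:`load_panel_fixture`.

Genotypes over a panel are represented as alternate-allele dosages per marker
(0 = hom-ref, 1 = het, 2 = hom-alt, NaN = missing), the natural encoding for
end-point fluorescence assays (KASP/PACE) once calls are polarised against the
panel's reference alleles.

Phasing follows Clark's parsimony scheme: fully homozygous, fully typed
individuals seed the known-haplotype set; heterozygotes are then resolved
against it, inferring at most one new complement at a time, with explicit
unresolved states (never guesses) when a genotype admits several explanations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, PanelError, RegistryError

__all__ = [
    "MarkerDef",
    "Panel",
    "Haplotype",
    "HaplotypeRegistry",
    "PhaseResult",
    "load_panel_fixture",
    "load_region_genes",
    "haplotypes_from_homozygotes",
    "clark_phase",
    "nonsyn_projection",
    "projection_classes",
    "hamming",
]

_EFFECTS = {"missense", "synonymous", "splice_region"}

# sha256 of the packaged fixture files; guards against silent edits.
_FIXTURE_SHA256 = {
    "cd99_panel.csv": "993bc76c2820e2f60400db31a830ccb2babc03adc2a765a6517d444f95ccb7e6",
    "cd99_haplotypes.csv": "4f194254e143e1e6617a2a662501832ac22ee3a57dbe2f04698c9ae455939355",
    "region_membrane_genes.csv": "2934e3227d49f85c0f023453fbf57a01cb2fb617ba1a5fdf192ebface166c355",
}


@dataclass(frozen=True)
class MarkerDef:
    """One panel assay: genomic position, alleles, and coding consequence.

    Positions are 1-based (GRCg6a). ``gene_location`` is the exon number as a
    string, or ``"intron"``. Indels are coded as biallelic markers with the
    allele symbols ``ref``/``del``.
    """

    assay_id: str
    chrom: str
    position: int
    gene_location: str
    ref_allele: str
    alt_allele: str
    variant_class: str = "snp"
    coding_effect: str = "synonymous"
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.coding_effect not in _EFFECTS:
            raise PanelError(
                f"{self.assay_id}: unknown coding effect {self.coding_effect!r}"
            )
        if self.coding_effect == "missense" and not self.aa_change:
            raise PanelError(f"{self.assay_id}: missense marker needs an aa_change")
        if self.variant_class == "indel" and {self.ref_allele, self.alt_allele} != {
            "ref",
            "del",
        }:
            raise PanelError(
                f"{self.assay_id}: indel alleles must be coded as ref/del"
            )


class Panel:
    """Ordered marker panel; order follows the assay design, not genomic order."""

    def __init__(self, markers: Sequence[MarkerDef], name: str = "panel"):
        self.markers: tuple[MarkerDef, ...] = tuple(markers)
        self.name = name
        if not self.markers:
            raise PanelError("panel must contain at least one marker")
        positions = [(m.chrom, m.position) for m in self.markers]
        if len(set(positions)) != len(positions):
            raise PanelError("duplicate marker positions in panel")
        ids = [m.assay_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate assay ids in panel")
        self._index = {m.assay_id: i for i, m in enumerate(self.markers)}

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def assay_ids(self) -> list[str]:
        return [m.assay_id for m in self.markers]

    def index(self, assay_id: str) -> int:
        try:
            return self._index[assay_id]
        except KeyError:
            raise PanelError(f"unknown assay id {assay_id!r}") from None

    def site_indices(self, site_filter: str = "all") -> list[int]:
        """Indices of markers passing a coding-effect filter.

        ``site_filter`` is one of ``all``, ``missense``, ``synonymous``.
        """
        if site_filter == "all":
            return list(range(len(self.markers)))
        if site_filter not in _EFFECTS:
            raise PanelError(f"unknown site filter {site_filter!r}")
        return [
            i for i, m in enumerate(self.markers) if m.coding_effect == site_filter
        ]

    @property
    def missense_indices(self) -> list[int]:
        return self.site_indices("missense")

    def encode(self, alleles: Sequence[str]) -> tuple[int, ...]:
        """Allele-string vector -> 0/1 (ref/alt) vector."""
        if len(alleles) != len(self.markers):
            raise PanelError(
                f"allele vector length {len(alleles)} != panel length {len(self)}"
            )
        bits = []
        for m, a in zip(self.markers, alleles):
            if a == m.ref_allele:
                bits.append(0)
            elif a == m.alt_allele:
                bits.append(1)
            else:
                raise PanelError(f"{m.assay_id}: allele {a!r} is neither ref nor alt")
        return tuple(bits)

    def decode(self, bits: Sequence[int]) -> tuple[str, ...]:
        if len(bits) != len(self.markers):
            raise PanelError("bit vector length mismatch")
        return tuple(
            m.alt_allele if b else m.ref_allele for m, b in zip(self.markers, bits)
        )


@dataclass(frozen=True)
class Haplotype:
    """A labelled allele vector over a panel."""

    label: str
    alleles: tuple[str, ...]


class HaplotypeRegistry:
    """Stable label <-> allele-vector registry over one panel.

    Labels are never renumbered; newly discovered vectors receive the next
    index after the highest one already used (gaps are preserved).
    """

    def __init__(self, panel: Panel, prefix: str = "CD99"):
        self.panel = panel
        self.prefix = prefix
        self._by_label: dict[str, Haplotype] = {}
        self._by_vector: dict[tuple[str, ...], str] = {}

    def __len__(self) -> int:
        return len(self._by_label)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def labels(self) -> list[str]:
        return list(self._by_label)

    def get(self, label: str) -> Haplotype:
        try:
            return self._by_label[label]
        except KeyError:
            raise RegistryError(f"unknown haplotype label {label!r}") from None

    def label_of(self, alleles: Sequence[str]) -> str | None:
        return self._by_vector.get(tuple(alleles))

    def add(self, label: str, alleles: Sequence[str]) -> Haplotype:
        vec = tuple(alleles)
        self.panel.encode(vec)  # validates alphabet and length
        if label in self._by_label:
            if self._by_label[label].alleles != vec:
                raise RegistryError(f"label collision: {label} already registered "
                                    "with a different allele vector")
            return self._by_label[label]
        if vec in self._by_vector:
            raise RegistryError(
                f"vector already registered as {self._by_vector[vec]}; "
                f"refusing second label {label}"
            )
        hap = Haplotype(label, vec)
        self._by_label[label] = hap
        self._by_vector[vec] = label
        return hap

    def _next_index(self) -> int:
        used = []
        tag = f"{self.prefix}-H"
        for label in self._by_label:
            if label.startswith(tag):
                try:
                    used.append(int(label[len(tag):]))
                except ValueError:
                    continue
        return max(used, default=0) + 1

    def register(self, vectors: Iterable[Sequence[str]]) -> list[str]:
        """Label new vectors in input order; known vectors keep their labels."""
        out = []
        for vec in vectors:
            vec = tuple(vec)
            existing = self.label_of(vec)
            if existing is not None:
                out.append(existing)
                continue
            label = f"{self.prefix}-H{self._next_index():02d}"
            self.add(label, vec)
            out.append(label)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": h.label, **dict(zip(self.panel.assay_ids, h.alleles))}
            for h in self._by_label.values()
        ]
        return pd.DataFrame(rows)


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("alloanchor.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise IntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {_FIXTURE_SHA256[name]}"
        )
    return data


def load_panel_fixture() -> tuple[Panel, HaplotypeRegistry, dict[str, str]]:
    """Load the packaged CD99 panel (7 SNPs + 1 splice-region indel, exons
    2-11) together with the 11-haplotype registry and the known haplotype ->
    serological-allele assignments (D1/D2/D3; unassigned haplotypes omitted).
    """
    import io

    panel_df = pd.read_csv(io.BytesIO(_fixture_bytes("cd99_panel.csv")), dtype=str)
    markers = [
        MarkerDef(
            assay_id=r.assay_id,
            chrom=r.chrom,
            position=int(r.position),
            gene_location=r.gene_location,
            ref_allele=r.ref_allele,
            alt_allele=r.alt_allele,
            variant_class=r.variant_class,
            coding_effect=r.coding_effect,
            aa_change=None if pd.isna(r.aa_change) else r.aa_change,
        )
        for r in panel_df.itertuples()
    ]
    panel = Panel(markers, name="CD99")
    hap_df = pd.read_csv(io.BytesIO(_fixture_bytes("cd99_haplotypes.csv")), dtype=str)
    registry = HaplotypeRegistry(panel, prefix="CD99")
    serology: dict[str, str] = {}
    for r in hap_df.itertuples():
        alleles = tuple(hap_df.loc[r.Index, a] for a in panel.assay_ids)
        registry.add(r.label, alleles)
        if isinstance(r.serology, str) and r.serology:
            serology[r.label] = r.serology
    return panel, registry, serology


def load_region_genes() -> pd.DataFrame:
    """Membrane-annotated genes of the chromosome-1 candidate region.

    Gene symbols and GO component terms follow the published region summary;
    the spans are representative placements within the mapped 129.7-131.4 Mb
    interval (exact coordinates were not part of the panel design), with the
    CD99 span taken from the panel's own marker positions.
    """
    import io

    df = pd.read_csv(io.BytesIO(_fixture_bytes("region_membrane_genes.csv")), dtype=str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# genotype handling and phasing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseResult:
    """Phasing outcome for one individual.

    ``haplotypes`` is the (sorted) label pair when resolved; otherwise
    ``candidates`` lists the competing label pairs (may be empty when no
    explanation exists within the known set).
    """

    individual_id: str
    resolved: bool
    haplotypes: tuple[str, str] | None = None
    candidates: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def _genotype_rows(genotypes: pd.DataFrame, panel: Panel) -> dict[str, tuple]:
    """DataFrame (individuals x assay ids, alt dosages) -> id -> tuple rows."""
    from .errors import FormatError

    missing_cols = [a for a in panel.assay_ids if a not in genotypes.columns]
    if missing_cols:
        raise FormatError(f"genotype table lacks panel columns: {missing_cols}")
    sub = genotypes[panel.assay_ids]
    rows: dict[str, tuple] = {}
    for ind, row in sub.iterrows():
        vals = []
        for a, v in zip(panel.assay_ids, row):
            if pd.isna(v):
                vals.append(None)
            else:
                iv = int(v)
                if iv not in (0, 1, 2):
                    raise FormatError(
                        f"individual {ind!r}, marker {a}: dosage {v!r} outside "
                        "{0,1,2,missing}"
                    )
                vals.append(iv)
        rows[str(ind)] = tuple(vals)
    return rows


def haplotypes_from_homozygotes(
    genotypes: pd.DataFrame, panel: Panel
) -> list[tuple[str, ...]]:
    """Haplotype vectors contributed by fully typed, fully homozygous rows.

    Each individual with no missing call and no heterozygous call carries two
    copies of a single haplotype, which is read off directly. Duplicates are
    merged; first-seen order is preserved.
    """
    seen: dict[tuple, None] = {}
    for _, g in _genotype_rows(genotypes, panel).items():
        if any(v is None for v in g) or any(v == 1 for v in g):
            continue
        vec = panel.decode(tuple(v // 2 for v in g))
        seen.setdefault(vec, None)
    return list(seen)


def _compatible_pairs(g: tuple, known: list[tuple[int, ...]]):
    """All unordered known-pair explanations of a genotype (non-missing sites)."""
    pairs = []
    for i, h1 in enumerate(known):
        for h2 in known[i:]:
            if all(gv is None or h1[k] + h2[k] == gv for k, gv in enumerate(g)):
                pairs.append((h1, h2))
    return pairs


def _novel_explanations(g: tuple, known: list[tuple[int, ...]]):
    """Distinct (known, new-complement) explanations for a complete genotype."""
    out = {}
    for h in known:
        comp = []
        ok = True
        for k, gv in enumerate(g):
            c = gv - h[k]
            if c not in (0, 1):
                ok = False
                break
            comp.append(c)
        if ok:
            comp_t = tuple(comp)
            pair = tuple(sorted((h, comp_t)))
            out[pair] = comp_t
    return out


def clark_phase(
    genotypes: pd.DataFrame,
    registry: HaplotypeRegistry,
) -> list[PhaseResult]:
    """Resolve panel genotypes into haplotype pairs by Clark parsimony.

    Individuals are processed in ascending order of heterozygous-site count,
    ties broken by individual id, repeatedly until no further resolution is
    possible. An individual resolves when exactly one pair of known haplotypes
    explains its genotype, or (for complete genotypes) when exactly one known
    haplotype plus a single new complement does; the complement then joins the
    registry. Genotypes admitting two or more known-pair explanations are
    reported unresolved with the candidate pairs listed. Results are returned
    in processing order.

    The registry is augmented in place; newly inferred vectors are labelled in
    discovery order.
    """
    panel = registry.panel
    rows = _genotype_rows(genotypes, panel)
    order = sorted(
        rows,
        key=lambda ind: (sum(1 for v in rows[ind] if v == 1), ind),
    )
    known_bits: list[tuple[int, ...]] = [
        panel.encode(registry.get(lbl).alleles) for lbl in registry.labels
    ]
    known_set = set(known_bits)

    results: dict[str, PhaseResult] = {}

    def label_for(bits: tuple[int, ...]) -> str:
        vec = panel.decode(bits)
        existing = registry.label_of(vec)
        if existing is not None:
            return existing
        return registry.register([vec])[0]

    pending = list(order)
    while True:
        progressed = False
        still_pending = []
        for ind in pending:
            g = rows[ind]
            pairs = _compatible_pairs(g, known_bits)
            if len(pairs) >= 2:
                cands = tuple(
                    tuple(sorted((label_for(a), label_for(b)))) for a, b in pairs
                )
                results[ind] = PhaseResult(ind, False, candidates=cands)
                progressed = True
                continue
            if len(pairs) == 1:
                a, b = pairs[0]
                results[ind] = PhaseResult(
                    ind, True, tuple(sorted((label_for(a), label_for(b))))
                )
                progressed = True
                continue
            if any(v is None for v in g):
                still_pending.append(ind)  # only known-pair resolution allowed
                continue
            if all(v in (0, 2) for v in g):
                # fully homozygous: the single carried haplotype seeds the set
                h = tuple(v // 2 for v in g)
                if h not in known_set:
                    known_bits.append(h)
                    known_set.add(h)
                lbl = label_for(h)
                results[ind] = PhaseResult(ind, True, (lbl, lbl))
                progressed = True
                continue
            novel = _novel_explanations(g, known_bits)
            if len(novel) == 1:
                (pair, comp) = next(iter(novel.items()))
                if comp not in known_set:
                    known_bits.append(comp)
                    known_set.add(comp)
                results[ind] = PhaseResult(
                    ind, True, tuple(sorted((label_for(pair[0]), label_for(pair[1]))))
                )
                progressed = True
            else:
                still_pending.append(ind)
        pending = still_pending
        if not pending or not progressed:
            break

    for ind in pending:  # exhausted: report what the known set can say
        g = rows[ind]
        pairs = _compatible_pairs(g, known_bits)
        if any(v is None for v in g):
            novel = {}
        else:
            novel = _novel_explanations(g, known_bits)
        cand_pairs = {tuple(sorted(p)) for p in pairs} | set(novel)
        cands = tuple(
            sorted(
                tuple(sorted((label_for(a), label_for(b)))) for a, b in cand_pairs
            )
        )
        results[ind] = PhaseResult(ind, False, candidates=cands)

    return [results[ind] for ind in order]


def nonsyn_projection(
    hap: Haplotype | Sequence[str], panel: Panel
) -> tuple[str, ...]:
    """Protein-level allele pattern: the sub-vector at missense markers.

    Haplotypes with equal projections encode identical proteins over the panel
    and cannot be distinguished serologically.
    """
    idx = panel.missense_indices
    if not idx:
        raise PanelError("panel has no missense marker; projection undefined")
    alleles = hap.alleles if isinstance(hap, Haplotype) else tuple(hap)
    if len(alleles) != len(panel):
        raise PanelError("haplotype length does not match panel")
    return tuple(alleles[i] for i in idx)


def projection_classes(
    registry: HaplotypeRegistry, panel: Panel | None = None
) -> dict[tuple[str, ...], list[str]]:
    """Group registry labels by their non-synonymous projection."""
    panel = panel or registry.panel
    classes: dict[tuple[str, ...], list[str]] = {}
    for label in registry.labels:
        proj = nonsyn_projection(registry.get(label), panel)
        classes.setdefault(proj, []).append(label)
    return classes


def hamming(
    h1: Haplotype | Sequence[str],
    h2: Haplotype | Sequence[str],
    panel: Panel,
    site_filter: str = "all",
) -> tuple[int, list[str]]:
    """Number of differing markers (under a coding-effect filter) and their ids."""
    a1 = h1.alleles if isinstance(h1, Haplotype) else tuple(h1)
    a2 = h2.alleles if isinstance(h2, Haplotype) else tuple(h2)
    if len(a1) != len(panel) or len(a2) != len(panel):
        raise PanelError("haplotype length does not match panel")
    idx = panel.site_indices(site_filter)
    diff = [panel.markers[i].assay_id for i in idx if a1[i] != a2[i]]
    return len(diff), diff


def diplotype_dosages(
    diplotype: tuple[str, str], registry: HaplotypeRegistry
) -> np.ndarray:
    """Alt-allele dosage vector implied by a pair of registered haplotypes."""
    panel = registry.panel
    b1 = panel.encode(registry.get(diplotype[0]).alleles)
    b2 = panel.encode(registry.get(diplotype[1]).alleles)
    return np.array(b1) + np.array(b2)
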