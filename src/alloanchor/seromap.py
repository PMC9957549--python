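"""Haplotype -> serological-allele assignment and concordance auditing.

Anchoring: a line that is serologically fixed for allele S and carries exactly
one panel haplotype H pins H -> S. Extension: remaining haplotypes are
assigned to remaining serological names by exhaustive search over injective
assignments, keeping the one that maximises exact diplotype agreement with the
serology records; ties are reported, never guessed. Haplotypes that encode the
same protein (equal non-synonymous projection) may share one serological name,
and an unmapped haplotype inherits the allele of its protein class when that
class is already consistently mapped.

The concordance audit translates each individual's SNP-defined diplotype
through the map and compares it, as an unordered pair, with the serology
record, classifying every disagreement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import MappingError
from .haplotypes import HaplotypeRegistry, projection_classes
from .screen import LineProfile

__all__ = [
    "SerologyRecord",
    "MapEntry",
    "HaplotypeSerologyMap",
    "Observation",
    "ConcordanceReport",
    "anchor_map",
    "cosegregation_extend",
    "concordance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SerologyRecord:
    """Serological typing of one individual: one or two allele names.

    A single-allele record means only one allele was detected; ``partial``
    marks "X and/or Y" typings, where the record lists the compatible names
    rather than a definite genotype.
    """

    individual_id: str
    line_id: str
    alleles: tuple[str, ...]
    partial: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("serology record must carry 1 or 2 alleles")


@dataclass(frozen=True)
class MapEntry:
    allele: str
    provenance: str  # "anchor" | "cosegregation"

    def __post_init__(self) -> None:
        if self.provenance not in {"anchor", "cosegregation"}:
            raise ValueError(f"bad provenance {self.provenance!r}")


class HaplotypeSerologyMap:
    """Mapping haplotype label -> serological allele, with provenance.

    Several haplotypes may share one allele; one haplotype never maps to two.
    Anchor entries are immutable: any attempt to overwrite one with a
    different allele raises :class:`MappingError`.
    """

    def __init__(self, entries: Mapping[str, MapEntry] | None = None):
        self._entries: dict[str, MapEntry] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __iter__(self):
        return iter(self._entries)

    @property
    def entries(self) -> dict[str, MapEntry]:
        return dict(self._entries)

    def allele_of(self, label: str) -> str:
        try:
            return self._entries[label].allele
        except KeyError:
            raise MappingError(f"haplotype {label} is not mapped") from None

    def mapped_alleles(self) -> set[str]:
        return {e.allele for e in self._entries.values()}

    def add(self, label: str, allele: str, provenance: str) -> None:
        existing = self._entries.get(label)
        if existing is not None:
            if existing.allele != allele:
                raise MappingError(
                    f"conflict for {label}: {existing.allele} "
                    f"({existing.provenance}) vs {allele} ({provenance})"
                )
            if existing.provenance == "anchor":
                return  # anchors are never downgraded
            if provenance == "anchor":
                self._entries[label] = MapEntry(allele, "anchor")
            return
        self._entries[label] = MapEntry(allele, provenance)

    def translate(self, diplotype: tuple[str, str]) -> tuple[str, str]:
        return tuple(sorted((self.allele_of(diplotype[0]),
                             self.allele_of(diplotype[1]))))

    def to_rows(self) -> list[dict]:
        return [
            {"haplotype": h, "allele": e.allele, "provenance": e.provenance}
            for h, e in sorted(self._entries.items())
        ]


@dataclass(frozen=True)
class Observation:
    """One individual's SNP-defined diplotype plus its serology record."""

    individual_id: str
    diplotype: tuple[str, str]
    serology: SerologyRecord


def anchor_map(
    profiles: Sequence[LineProfile],
    line_haplotypes: Mapping[str, Iterable[str]],
) -> HaplotypeSerologyMap:
    """Pin haplotypes to alleles from serologically fixed, monomorphic lines.

    Each line that is fixed for allele S and carries exactly one haplotype H
    contributes the anchor H -> S. Lines fixed serologically but carrying two
    or more haplotypes are ambiguous and contribute nothing. Two lines
    anchoring the same haplotype to the same allele merge silently; to
    different alleles, a :class:`MappingError` lists the evidence.
    """
    m = HaplotypeSerologyMap()
    for p in profiles:
        if p.status != "fixed":
            continue
        haps = set(line_haplotypes.get(p.line_id, ()))
        if len(haps) != 1:
            logger.info("anchor_map: line %s fixed but carries %d haplotypes; "
                        "skipped", p.line_id, len(haps))
            continue
        (h,) = haps
        allele = next(iter(p.known_alleles))
        try:
            m.add(h, allele, "anchor")
        except MappingError as err:
            raise MappingError(
                f"anchor conflict from line {p.line_id}: {err}"
            ) from None
    return m


def _agrees(translated: tuple[str, str], rec: SerologyRecord) -> bool:
    t = tuple(sorted(translated))
    if rec.partial:
        return set(t) <= set(rec.alleles)
    s = rec.alleles if len(rec.alleles) == 2 else (rec.alleles[0], rec.alleles[0])
    return tuple(sorted(s)) == t


def _classify(translated: tuple[str, str], rec: SerologyRecord) -> str:
    t = tuple(sorted(translated))
    if t[0] == t[1]:
        return "homozygote_misidentified"
    if len(rec.alleles) == 1 and rec.alleles[0] in t:
        return "second_allele_missed"
    return "second_allele_wrong"


@dataclass
class TieReport:
    tied_assignments: list[dict] = field(default_factory=list)
    score: int = 0


def cosegregation_extend(
    base: HaplotypeSerologyMap,
    observations: Sequence[Observation],
    registry: HaplotypeRegistry | None = None,
) -> tuple[HaplotypeSerologyMap, dict]:
    """Extend an anchored map by protein-class inheritance and co-segregation.

    First, any unmapped haplotype whose non-synonymous protein class (from
    ``registry``) already maps consistently to a single allele inherits that
    allele. Then all injective assignments of the remaining unmapped
    haplotypes (seen in the observations) to the serological names not yet in
    the map's image are scored by the number of observations whose translated
    diplotype exactly agrees with the serology record; the unique maximiser is
    adopted. A tie adds nothing and is reported; haplotypes with no covering
    observation stay unmapped and are listed.
    """
    m = HaplotypeSerologyMap(base.entries)
    report: dict = {"inherited": [], "assigned": [], "ties": None, "uncovered": []}

    if registry is not None:
        classes = projection_classes(registry)
        for proj, members in classes.items():
            mapped = {m.allele_of(l) for l in members if l in m}
            if len(mapped) == 1:
                allele = next(iter(mapped))
                for l in members:
                    if l not in m:
                        m.add(l, allele, "cosegregation")
                        report["inherited"].append({"haplotype": l, "allele": allele})

    seen_haps: list[str] = []
    for obs in observations:
        for h in obs.diplotype:
            if h not in seen_haps:
                seen_haps.append(h)
    unmapped = [h for h in seen_haps if h not in m]
    names_seen: list[str] = []
    for obs in observations:
        for a in obs.serology.alleles:
            if a not in names_seen:
                names_seen.append(a)
    free_names = [a for a in names_seen if a not in m.mapped_alleles()]

    covered = [h for h in unmapped
               if any(h in o.diplotype for o in observations)]
    report["uncovered"] = [h for h in unmapped if h not in covered]
    for h in report["uncovered"]:
        logger.info("cosegregation_extend: no observation covers %s", h)

    if not covered or not free_names:
        return m, report

    k = min(len(covered), len(free_names))

    def score(assign: dict) -> int:
        trial = HaplotypeSerologyMap(m.entries)
        for h, a in assign.items():
            trial.add(h, a, "cosegregation")
        s = 0
        for obs in observations:
            try:
                t = trial.translate(obs.diplotype)
            except MappingError:
                continue
            if _agrees(t, obs.serology):
                s += 1
        return s

    best_score = -1
    best: list[dict] = []
    for hap_subset in itertools.combinations(covered, k):
        for name_perm in itertools.permutations(free_names, k):
            assign = dict(zip(hap_subset, name_perm))
            s = score(assign)
            if s > best_score:
                best_score, best = s, [assign]
            elif s == best_score:
                best.append(assign)

    if len(best) == 1:
        for h, a in best[0].items():
            m.add(h, a, "cosegregation")
            report["assigned"].append({"haplotype": h, "allele": a})
    else:
        report["ties"] = {"score": best_score, "assignments": best}
        logger.info("cosegregation_extend: %d tied assignments at score %d; "
                    "nothing adopted", len(best), best_score)
    return m, report


@dataclass
class ConcordanceReport:
    """Agreement between SNP-derived and serology-derived genotypes."""

    n_total: int
    n_agree: int
    classes: dict
    per_line: dict
    n_partial: int = 0

    @property
    def fraction(self) -> float:
        return self.n_agree / self.n_total if self.n_total else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_agree": self.n_agree,
            "fraction": self.fraction,
            "classes": dict(self.classes),
            "per_line": {k: dict(v) for k, v in self.per_line.items()},
            "n_partial": self.n_partial,
        }


def concordance(
    m: HaplotypeSerologyMap, observations: Sequence[Observation]
) -> ConcordanceReport:
    """Audit agreement between translated diplotypes and serology records.

    Agreement is exact unordered-pair identity; a single-allele record agrees
    with the matching homozygote, and a partial ("and/or") record agrees with
    any compatible pair. Disagreements are classified as second_allele_missed
    (one allele reported, present in the translated pair),
    homozygote_misidentified (translated pair homozygous, serology
    heterozygous or disjoint), or second_allele_wrong otherwise.
    """
    classes = {
        "second_allele_missed": 0,
        "second_allele_wrong": 0,
        "homozygote_misidentified": 0,
    }
    per_line: dict[str, dict] = {}
    n_agree = 0
    n_partial = 0
    for obs in observations:
        try:
            t = m.translate(obs.diplotype)
        except MappingError as err:
            raise MappingError(
                f"individual {obs.individual_id}: {err}"
            ) from None
        line = obs.serology.line_id
        stats = per_line.setdefault(line, {"n": 0, "agree": 0})
        stats["n"] += 1
        if obs.serology.partial:
            n_partial += 1
        if _agrees(t, obs.serology):
            n_agree += 1
            stats["agree"] += 1
        else:
            classes[_classify(t, obs.serology)] += 1
    return ConcordanceReport(
        n_total=len(observations),
        n_agree=n_agree,
        classes=classes,
        per_line=per_line,
        n_partial=n_partial,
    )
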