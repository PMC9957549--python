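"""Panel fixture, registries, projections, distances, and Clark phasing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alloanchor.errors import PanelError, RegistryError
from alloanchor.haplotypes import (
    HaplotypeRegistry,
    MarkerDef,
    Panel,
    clark_phase,
    diplotype_dosages,
    hamming,
    haplotypes_from_homozygotes,
    nonsyn_projection,
    projection_classes,
)


def hap(reg, short):
    return reg.get(f"CD99-{short}")


class TestFixture:
    def test_registry_holds_eleven_distinct_haplotypes(self, fixture_panel):
        panel, reg, _ = fixture_panel
        assert len(reg) == 11
        vectors = {reg.get(l).alleles for l in reg.labels}
        assert len(vectors) == 11

    def test_panel_has_seven_snps_and_one_indel(self, fixture_panel):
        panel, _, _ = fixture_panel
        classes = [m.variant_class for m in panel.markers]
        assert classes.count("snp") == 7
        assert classes.count("indel") == 1

    def test_marker_positions_and_order(self, fixture_panel):
        panel, _, _ = fixture_panel
        assert panel.markers[0].assay_id == "rs74153692"
        assert panel.markers[0].position == 129_875_094
        # assay order follows exon numbering; positions decrease along the gene
        snp_pos = [m.position for m in panel.markers if m.variant_class == "snp"]
        assert snp_pos == sorted(snp_pos, reverse=True)

    def test_serology_assignments(self, fixture_panel):
        _, _, sero = fixture_panel
        assert sero == {
            "CD99-H01": "D1",
            "CD99-H02": "D2",
            "CD99-H03": "D3",
            "CD99-H04": "D3",
            "CD99-H06": "D3",
        }

    def test_pairwise_hamming_at_least_one(self, fixture_panel):
        panel, reg, _ = fixture_panel
        for a, b in itertools.combinations(reg.labels, 2):
            n, _ = hamming(reg.get(a), reg.get(b), panel)
            assert n >= 1


class TestProjection:
    def test_h06_protein_identical_to_h03(self, fixture_panel):
        panel, reg, _ = fixture_panel
        assert nonsyn_projection(hap(reg, "H06"), panel) == nonsyn_projection(
            hap(reg, "H03"), panel
        )
        n, _ = hamming(hap(reg, "H06"), hap(reg, "H03"), panel, "missense")
        assert n == 0

    def test_partition_matches_bruteforce_grouping(self, fixture_panel):
        """Grouping raw haplotype columns at missense rows reproduces the
        projection partition: 5 protein classes."""
        panel, reg, _ = fixture_panel
        missense = [i for i, m in enumerate(panel.markers)
                    if m.coding_effect == "missense"]
        brute = {}
        for l in reg.labels:
            key = tuple(reg.get(l).alleles[i] for i in missense)
            brute.setdefault(key, set()).add(l)
        classes = {k: set(v) for k, v in projection_classes(reg).items()}
        assert classes == brute
        assert len(classes) == 5
        assert {frozenset(v) for v in classes.values()} == {
            frozenset({"CD99-H01", "CD99-H11"}),
            frozenset({"CD99-H02"}),
            frozenset({"CD99-H03", "CD99-H04", "CD99-H06", "CD99-H08",
                       "CD99-H10"}),
            frozenset({"CD99-H05", "CD99-H09"}),
            frozenset({"CD99-H07"}),
        }

    def test_projection_idempotent(self, fixture_panel):
        panel, reg, _ = fixture_panel
        sub_markers = [panel.markers[i] for i in panel.missense_indices]
        sub_panel = Panel(sub_markers, "missense-only")
        for l in reg.labels:
            proj = nonsyn_projection(reg.get(l), panel)
            assert nonsyn_projection(proj, sub_panel) == proj

    def test_projection_requires_missense_marker(self, fixture_panel):
        panel, reg, _ = fixture_panel
        syn_only = Panel(
            [m for m in panel.markers if m.coding_effect == "synonymous"],
            "syn",
        )
        with pytest.raises(PanelError):
            nonsyn_projection(tuple("ACGT"[:len(syn_only)] for _ in syn_only.markers),
                              syn_only)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,site",
        [
            ("H11", "H01", "rs735519530"),  # one synonymous SNP (L185L)
            ("H10", "H04", "rs316308207"),  # one synonymous SNP (G95G)
        ],
    )
    def test_single_synonymous_difference(self, fixture_panel, a, b, site):
        panel, reg, _ = fixture_panel
        n, sites = hamming(hap(reg, a), hap(reg, b), panel)
        assert (n, sites) == (1, [site])
        assert panel.markers[panel.index(site)].coding_effect == "synonymous"

    def test_identity_is_zero_under_any_filter(self, fixture_panel):
        panel, reg, _ = fixture_panel
        for f in ("all", "missense", "synonymous"):
            assert hamming(hap(reg, "H07"), hap(reg, "H07"), panel, f) == (0, [])


class TestRegistry:
    def test_reregistering_keeps_label(self, fixture_panel):
        panel, reg, _ = fixture_panel
        vec = reg.get("CD99-H03").alleles
        assert reg.register([vec]) == ["CD99-H03"]

    def test_novel_vector_gets_successor_label(self, fixture_panel):
        panel, reg, _ = fixture_panel
        fresh = HaplotypeRegistry(panel, prefix="CD99")
        for l in reg.labels:
            fresh.add(l, reg.get(l).alleles)
        novel = list(reg.get("CD99-H03").alleles)
        novel[0] = panel.markers[0].alt_allele  # V27M flip: not in registry
        novel2 = list(reg.get("CD99-H02").alleles)
        novel2[-1] = panel.markers[-1].alt_allele
        labels = fresh.register([tuple(novel), tuple(novel2)])
        assert labels == ["CD99-H12", "CD99-H13"]  # input order

    def test_label_collision_raises(self, fixture_panel):
        panel, reg, _ = fixture_panel
        fresh = HaplotypeRegistry(panel)
        fresh.add("CD99-H01", reg.get("CD99-H01").alleles)
        with pytest.raises(RegistryError):
            fresh.add("CD99-H01", reg.get("CD99-H02").alleles)
        with pytest.raises(RegistryError):
            fresh.add("CD99-H99", reg.get("CD99-H01").alleles)


def genotype_frame(reg, diplotypes):
    """Build a genotype table from {individual: (labelA, labelB)}."""
    panel = reg.panel
    rows = {
        ind: diplotype_dosages(pair, reg) for ind, pair in diplotypes.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=panel.assay_ids)


class TestHomozygoteExtraction:
    def test_homozygote_contributes_single_haplotype(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(reg, {"a": ("CD99-H03", "CD99-H03")})
        assert haplotypes_from_homozygotes(g, panel) == [
            reg.get("CD99-H03").alleles
        ]

    def test_heterozygote_contributes_nothing(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(reg, {"a": ("CD99-H01", "CD99-H03")})
        assert haplotypes_from_homozygotes(g, panel) == []

    def test_incomplete_homozygote_excluded(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(reg, {"a": ("CD99-H03", "CD99-H03")}).astype(float)
        g.iloc[0, 0] = np.nan
        assert haplotypes_from_homozygotes(g, panel) == []

    def test_fixed_line_yields_exactly_its_haplotype(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(
            reg, {f"i{k}": ("CD99-H03", "CD99-H03") for k in range(20)}
        )
        assert haplotypes_from_homozygotes(g, panel) == [
            reg.get("CD99-H03").alleles
        ]


class TestClarkPhase:
    def test_het_resolved_against_known_homozygote_haplotypes(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(
            reg,
            {
                "hom1": ("CD99-H01", "CD99-H01"),
                "hom3": ("CD99-H03", "CD99-H03"),
                "het": ("CD99-H01", "CD99-H03"),
            },
        )
        fresh = HaplotypeRegistry(panel, prefix="CD99")
        res = {p.individual_id: p for p in clark_phase(g, fresh)}
        assert res["het"].resolved
        v1, v2 = (fresh.get(l).alleles for l in res["het"].haplotypes)
        assert {v1, v2} == {reg.get("CD99-H01").alleles,
                            reg.get("CD99-H03").alleles}

    def test_ambiguous_genotype_reports_candidates(self, fixture_panel):
        """H04+H09 and H05+H08 imply identical genotypes; with all four known
        the individual must stay unresolved, listing exactly the pairs a
        brute-force pair enumeration finds."""
        panel, reg, _ = fixture_panel
        g = genotype_frame(reg, {"amb": ("CD99-H04", "CD99-H09")})
        res = clark_phase(g, reg)[0]
        assert not res.resolved
        # independent oracle: enumerate all registry pairs
        target = tuple(g.loc["amb"])
        expected = set()
        for a, b in itertools.combinations_with_replacement(reg.labels, 2):
            if tuple(diplotype_dosages((a, b), reg)) == target:
                expected.add(tuple(sorted((a, b))))
        assert set(res.candidates) == expected
        assert len(expected) >= 2

    def test_unique_known_pair_beats_novel_explanations(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(reg, {"x": ("CD99-H02", "CD99-H03")})
        res = clark_phase(g, reg)[0]
        assert res.resolved
        assert res.haplotypes == ("CD99-H02", "CD99-H03")

    def test_new_complement_is_inferred_and_registered(self, fixture_panel):
        panel, reg, _ = fixture_panel
        g = genotype_frame(
            reg,
            {
                "hom3a": ("CD99-H03", "CD99-H03"),
                "het36": ("CD99-H03", "CD99-H06"),
            },
        )
        fresh = HaplotypeRegistry(panel, prefix="CD99")
        res = {p.individual_id: p for p in clark_phase(g, fresh)}
        assert res["het36"].resolved
        vectors = {fresh.get(l).alleles for l in fresh.labels}
        assert reg.get("CD99-H06").alleles in vectors

    def test_resolved_diplotypes_reconstruct_genotypes(self, fixture_panel, rng):
        panel, reg, _ = fixture_panel
        labels = reg.labels
        diplos = {
            f"i{k}": tuple(sorted(rng.choice(labels, 2, replace=True)))
            for k in range(60)
        }
        g = genotype_frame(reg, diplos)
        for p in clark_phase(g, reg):
            if p.resolved:
                got = tuple(diplotype_dosages(p.haplotypes, reg))
                assert got == tuple(g.loc[p.individual_id])

    def test_row_order_invariance(self, fixture_panel, rng):
        panel, reg, _ = fixture_panel
        labels = ["CD99-H01", "CD99-H03", "CD99-H06"]
        diplos = {
            f"i{k}": tuple(sorted(rng.choice(labels, 2, replace=True)))
            for k in range(40)
        }
        g = genotype_frame(reg, diplos)
        shuffled = g.sample(frac=1.0, random_state=7)
        r1 = {p.individual_id: p for p in
              clark_phase(g, HaplotypeRegistry(panel, "CD99"))}
        r2 = {p.individual_id: p for p in
              clark_phase(shuffled, HaplotypeRegistry(panel, "CD99"))}
        for ind in diplos:
            assert r1[ind].resolved == r2[ind].resolved


class TestMarkerDefValidation:
    def test_missense_requires_aa_change(self):
        with pytest.raises(PanelError):
            MarkerDef("m1", "1", 100, "2", "G", "A", "snp", "missense", None)

    def test_indel_alleles_must_be_ref_del(self):
        with pytest.raises(PanelError):
            MarkerDef("m1", "1", 100, "intron", "G", "A", "indel",
                      "splice_region")
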