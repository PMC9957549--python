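"""Population, mating, serology-error, intensity and variant-table generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alloanchor.errors import ConfigurationError, MappingError
from alloanchor.haplotypes import diplotype_dosages
from alloanchor.screen import rank_candidates
from alloanchor.simulate import (
    Individual,
    LineSpec,
    SimConfig,
    default_config,
    generate_dataset,
    line_profiles_from_truth,
    mate,
    observe_serology,
    pool_intensity,
    sample_population,
    simulate_intensity,
    simulate_pool_experiment,
    simulate_variant_table,
    stage_rng,
    write_genotypes,
    write_population,
    write_serology,
)


def one_line_config(freqs, n=20, seed=0, status=None):
    if status is None:
        status = "fixed" if len([f for f in freqs.values() if f > 0]) == 1 \
            else "segregating"
    return SimConfig(
        seed=seed,
        lines=[LineSpec("L1", "WL", freqs, status)],
        n_individuals=n,
    )


class TestSamplePopulation:
    def test_degenerate_frequency_gives_monomorphic_line(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = one_line_config({"CD99-H03": 1.0})
        pop = sample_population(cfg, reg)
        assert len(pop) == 20
        assert all(i.diplotype == ("CD99-H03", "CD99-H03") for i in pop)

    def test_heterozygote_fraction_matches_hardy_weinberg(self, fixture_panel):
        _, reg, _ = fixture_panel
        n = 10_000
        cfg = one_line_config({"CD99-H01": 0.5, "CD99-H03": 0.5}, n=n, seed=5)
        pop = sample_population(cfg, reg)
        het = sum(i.diplotype[0] != i.diplotype[1] for i in pop) / n
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) <= 3 * se

    def test_line_partition_bookkeeping(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = SimConfig(
            seed=1,
            lines=[
                LineSpec("A", "WL", {"CD99-H01": 1.0}, "fixed"),
                LineSpec("B", "WL", {"CD99-H03": 1.0}, "fixed"),
            ],
            n_individuals=7,
        )
        pop = sample_population(cfg, reg)
        by_line = {}
        for i in pop:
            by_line.setdefault(i.line_id, []).append(i)
        assert {k: len(v) for k, v in by_line.items()} == {"A": 7, "B": 7}

    def test_unknown_haplotype_label_rejected(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = one_line_config({"CD99-H99": 1.0})
        with pytest.raises(ConfigurationError):
            sample_population(cfg, reg)

    def test_frequencies_must_sum_to_one(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = one_line_config({"CD99-H01": 0.6, "CD99-H03": 0.6})
        with pytest.raises(ConfigurationError):
            sample_population(cfg, reg)

    def test_reproducible_for_fixed_seed(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = one_line_config({"CD99-H01": 0.5, "CD99-H03": 0.5}, n=50, seed=9)
        a = sample_population(cfg, reg)
        b = sample_population(cfg, reg)
        assert a == b


class TestMate:
    def test_fixed_cross_is_monomorphic(self):
        p = Individual("s", "L", ("CD99-H01", "CD99-H01"))
        q = Individual("d", "L", ("CD99-H01", "CD99-H01"))
        prog = mate(p, q, 10, rng=1)
        assert all(c.diplotype == ("CD99-H01", "CD99-H01") for c in prog)
        assert all(c.sire_id == "s" and c.dam_id == "d" for c in prog)

    def test_intercross_segregates_1_2_1(self):
        p = Individual("s", "L", ("CD99-H01", "CD99-H02"))
        q = Individual("d", "L", ("CD99-H01", "CD99-H02"))
        prog = mate(p, q, 4000, rng=np.random.default_rng(3))
        counts = {"hom1": 0, "het": 0, "hom2": 0}
        for c in prog:
            if c.diplotype == ("CD99-H01", "CD99-H01"):
                counts["hom1"] += 1
            elif c.diplotype == ("CD99-H02", "CD99-H02"):
                counts["hom2"] += 1
            else:
                counts["het"] += 1
        chi2 = stats.chisquare(
            [counts["hom1"], counts["het"], counts["hom2"]],
            [1000, 2000, 1000],
        )
        assert chi2.pvalue > 0.01

    def test_backcross_support(self):
        p = Individual("s", "L", ("CD99-H01", "CD99-H02"))
        q = Individual("d", "L", ("CD99-H03", "CD99-H03"))
        prog = mate(p, q, 200, rng=7)
        seen = {c.diplotype for c in prog}
        assert seen <= {("CD99-H01", "CD99-H03"), ("CD99-H02", "CD99-H03")}

    def test_rejects_empty_family(self):
        p = Individual("s", "L", ("CD99-H01", "CD99-H01"))
        with pytest.raises(ValueError):
            mate(p, p, 0, rng=1)


class TestObserveSerology:
    MAP = {"CD99-H01": "D1", "CD99-H02": "D2", "CD99-H03": "D3"}

    def test_homozygote_never_misreported(self, rng):
        ind = Individual("i", "L", ("CD99-H03", "CD99-H03"))
        for _ in range(50):
            rec = observe_serology(ind, self.MAP, het_error=1.0, rng=rng)
            assert rec.alleles == ("D3", "D3")

    def test_heterozygote_exact_without_error(self, rng):
        ind = Individual("i", "L", ("CD99-H01", "CD99-H03"))
        rec = observe_serology(ind, self.MAP, het_error=0.0, rng=rng)
        assert rec.alleles == ("D1", "D3")

    def test_heterozygote_error_keeps_one_true_allele(self, rng):
        """With certain error, a D1/D3 heterozygote reads as a D1- or
        D3-homozygote-like record; D2 can never appear."""
        ind = Individual("i", "L", ("CD99-H01", "CD99-H03"))
        seen = set()
        for _ in range(200):
            rec = observe_serology(ind, self.MAP, het_error=1.0, rng=rng)
            assert set(rec.alleles) in ({"D1"}, {"D3"})
            seen.add((len(rec.alleles), rec.alleles[0]))
        # both kept alleles and both record shapes occur
        assert {a for _, a in seen} == {"D1", "D3"}
        assert {n for n, _ in seen} == {1, 2}

    def test_unmapped_haplotype_raises(self, rng):
        ind = Individual("i", "L", ("CD99-H01", "CD99-H07"))
        with pytest.raises(MappingError):
            observe_serology(ind, self.MAP, 0.0, rng)


class TestIntensity:
    def test_noiseless_intensity_is_half_dosage(self, rng):
        out = simulate_intensity([0, 1, 2], noise_sd=0.0, rng=rng)
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_missing_dosage_stays_missing(self, rng):
        out = simulate_intensity([2, np.nan], noise_sd=0.1, rng=rng)
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_noiseless_pool_is_mean_of_members(self, rng):
        members = simulate_intensity(
            np.array([[0.0], [1.0], [2.0]]), 0.0, rng
        )
        pool = pool_intensity(members, 0.0, rng)
        assert pool[0] == pytest.approx(0.5)

    def test_noise_sd_recovered(self, rng):
        draws = simulate_intensity(np.ones(10_000), noise_sd=0.05, rng=rng)
        assert abs(np.std(draws - 0.5, ddof=1) - 0.05) < 0.05 * 0.05

    def test_intensity_truncated_to_unit_interval(self, rng):
        out = simulate_intensity(np.full(1000, 2.0), 0.5, rng)
        assert np.nanmax(out) <= 1.0 and np.nanmin(out) >= 0.0


class TestPoolExperiment:
    def test_layout_and_expected_counts(self):
        cfg = default_config(seed=3)
        exp = simulate_pool_experiment(cfg)
        assert len(exp.pools) == 9
        assert sorted(exp.pools["expected_count"]) == [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert exp.pools["size"].between(3, 8).all()
        assert exp.intensities.shape == (9, cfg.n_background_snps + 1)

    def test_expected_count_equals_mean_member_dosage(self):
        """Pools are built from same-class members, so the serology-implied
        count equals the mean member dosage at the focal locus exactly."""
        cfg = default_config(seed=3)
        cfg.intensity_noise_sd = 0.0
        cfg.pool_noise_sd = 0.0
        exp = simulate_pool_experiment(cfg)
        np.testing.assert_allclose(
            exp.intensities["causal_snp"] * 2.0, exp.pools["expected_count"]
        )

    def test_deterministic_given_seed(self):
        cfg = default_config(seed=11)
        a = simulate_pool_experiment(cfg)
        b = simulate_pool_experiment(cfg)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)


class TestVariantTable:
    def test_fixed_line_column_has_no_hets_in_causal_gene(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = default_config(seed=0)
        variants, genes = simulate_variant_table(cfg, reg)
        causal = variants[variants["gene"] == cfg.causal_gene]
        for line in ("WL2", "WL5", "IAH7"):
            assert not (causal[line] == 1).any()

    def test_lines_fixed_for_same_allele_identical(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = default_config(seed=0)
        variants, _ = simulate_variant_table(cfg, reg)
        causal = variants[variants["gene"] == cfg.causal_gene]
        assert (causal["WL2"] == causal["WL5"]).all()
        assert (causal["WL2"].isin([0, 2])).all()

    def test_only_causal_gene_survives_both_screens(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = default_config(seed=0)
        variants, genes = simulate_variant_table(cfg, reg)
        profiles = line_profiles_from_truth(
            cfg, {"CD99-H01": "D1", "CD99-H02": "D2", "CD99-H03": "D3",
                  "CD99-H04": "D3", "CD99-H06": "D3"}
        )
        candidates, report = rank_candidates(genes, variants, profiles)
        assert candidates == [cfg.causal_gene]

    def test_region_too_small_raises(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = default_config(seed=0)
        cfg.causal_region = ("1", 129_700_000, 129_950_000)
        with pytest.raises(ConfigurationError):
            simulate_variant_table(cfg, reg)


class TestDatasetDeterminism:
    def test_written_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = default_config(seed=21, n_individuals=15)
        for d in ("a", "b"):
            data = generate_dataset(cfg)
            out = tmp_path / d
            out.mkdir()
            write_population(data.individuals, out / "population.csv")
            write_genotypes(data.genotypes, out / "genotypes.csv")
            write_serology(data.serology, out / "serology.csv")
        for name in ("population.csv", "genotypes.csv", "serology.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_serology_alleles_never_disjoint_from_truth(self, fixture_panel):
        _, reg, _ = fixture_panel
        cfg = default_config(seed=13, n_individuals=40)
        cfg.serology_het_error = 0.5
        data = generate_dataset(cfg)
        truth = {
            i.individual_id: {data.hap2sero[h] for h in i.diplotype}
            for i in data.individuals
            if all(h in data.hap2sero for h in i.diplotype)
        }
        for rec in data.serology:
            assert set(rec.alleles) & truth[rec.individual_id]

    def test_progeny_allele_frequency_converges(self, fixture_panel):
        """Law of large numbers: transmitted allele frequency from a
        heterozygous sire approaches 1/2."""
        _, reg, _ = fixture_panel
        sire = Individual("s", "L", ("CD99-H01", "CD99-H02"))
        dam = Individual("d", "L", ("CD99-H03", "CD99-H03"))
        prog = mate(sire, dam, 10_000, rng=np.random.default_rng(5))
        f_h01 = np.mean([c.diplotype[0] == "CD99-H01" for c in prog])
        assert abs(f_h01 - 0.5) < 3 * np.sqrt(0.25 / 10_000)
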