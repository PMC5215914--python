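"""Synthetic parental populations, hybrid-class simulators, study fixture."""

import numpy as np
import pytest

import hybridcensus as hc
from hybridcensus.simulate import HYBRID_CLASSES

from conftest import make_diagnostic_freqs


class TestParentalFrequencies:
    def test_realized_fst_near_target(self, study_conditions):
        """Sampling fresh populations from the calibrated tables lands near
        the target differentiation (checked with the FST estimator as
        independent oracle)."""
        cfg, freq_a, freq_b = study_conditions
        a = hc.sample_population(freq_a, 50, seed=901, group_label="A")
        b = hc.sample_population(freq_b, 50, seed=902, group_label="B")
        fst = hc.weir_cockerham_fst(a.concat(b), "A", "B").fst
        assert 0.22 <= fst <= 0.34  # target 0.28, calibration band + sampling noise

    def test_allele_counts_within_ranges(self, study_conditions):
        cfg, freq_a, freq_b = study_conditions
        for locus in freq_a.loci:
            assert 2 <= len(freq_a.freq("A", locus)) <= 5
            assert 2 <= len(freq_b.freq("B", locus)) <= 14

    def test_no_locus_fully_diagnostic(self, study_conditions):
        _, freq_a, freq_b = study_conditions
        for locus in freq_a.loci:
            assert set(freq_a.freq("A", locus)) & set(freq_b.freq("B", locus))

    def test_deterministic_under_seed(self):
        cfg = hc.SimulationConfig(seed=42)
        fa1, fb1 = hc.make_parental_frequencies(cfg)
        fa2, fb2 = hc.make_parental_frequencies(hc.SimulationConfig(seed=42))
        for locus in fa1.loci:
            assert fa1.freq("A", locus) == fa2.freq("A", locus)
            assert fb1.freq("B", locus) == fb2.freq("B", locus)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hc.SimulationConfig(seed=1, target_fst=1.5)


class TestSamplePopulation:
    def test_degenerate_frequency_all_homozygous(self):
        fa, _ = make_diagnostic_freqs(n_loci=3)
        ds = hc.sample_population(fa, 20, seed=1)
        for ind in ds.individuals:
            assert all(g == (101, 101) for g in ind.genotype)

    def test_heterozygosity_matches_hardy_weinberg(self):
        loci = ["L1"]
        fa = hc.FreqTable(("A",), loci, {("A", "L1"): {101: 0.75, 103: 0.25}}, {("A", "L1"): 100})
        ds = hc.sample_population(fa, 10_000, seed=2)
        het = np.mean([ind.genotype[0][0] != ind.genotype[0][1] for ind in ds.individuals])
        assert het == pytest.approx(2 * 0.75 * 0.25, abs=0.02)

    def test_seed_reproducibility(self, study_conditions):
        _, freq_a, _ = study_conditions
        d1 = hc.sample_population(freq_a, 10, seed=5)
        d2 = hc.sample_population(freq_a, 10, seed=5)
        assert d1 == d2

    def test_nonpositive_n_rejected(self, study_conditions):
        _, freq_a, _ = study_conditions
        with pytest.raises(ValueError):
            hc.sample_population(freq_a, 0, seed=1)


class TestFrequencySimulator:
    def test_f1_forced_heterozygote(self, diagnostic_freqs):
        fa, fb = diagnostic_freqs
        ds = hc.simulate_hybrid_class_frequency(fa, fb, "F1", 50, seed=3)
        for ind in ds.individuals:
            assert all(g == (101, 105) for g in ind.genotype)

    def test_f2_genotype_law(self, diagnostic_freqs):
        """F2 at a fixed-allele locus: AA 1/4, het 1/2, BB 1/4."""
        fa, fb = diagnostic_freqs
        ds = hc.simulate_hybrid_class_frequency(fa, fb, "F2", 2000, seed=4)
        geno = np.array([ind.genotype[0] for ind in ds.individuals])
        p_aa = np.mean((geno == 101).all(axis=1))
        p_bb = np.mean((geno == 105).all(axis=1))
        assert p_aa == pytest.approx(0.25, abs=0.03)
        assert p_bb == pytest.approx(0.25, abs=0.03)

    def test_bxa2_donor_allele_frequency(self, diagnostic_freqs):
        """Second backcross: donor-allele frequency 0.5*(0 + 0.25) = 0.125."""
        fa, fb = diagnostic_freqs
        ds = hc.simulate_hybrid_class_frequency(fa, fb, "BxA2", 1000, seed=5)
        alleles = np.array([g for ind in ds.individuals for g in ind.genotype])
        freq_b = (alleles == 105).mean()
        assert freq_b == pytest.approx(0.125, abs=3 * np.sqrt(0.125 * 0.875 / alleles.size))

    def test_class_mean_ancestry_tracks_expectation(self, diagnostic_freqs):
        """Mean donor-allele fraction matches 1 - expected A-ancestry (3 SE)."""
        fa, fb = diagnostic_freqs
        for cls, hclass in HYBRID_CLASSES.items():
            ds = hc.simulate_hybrid_class_frequency(fa, fb, cls, 100, seed=7)
            alleles = np.array([g for ind in ds.individuals for g in ind.genotype])
            frac_b = (alleles == 105).mean()
            expected = 1.0 - hclass.expected_a_ancestry
            se = np.sqrt(max(expected * (1 - expected), 1e-6) / alleles.size)
            assert abs(frac_b - expected) <= max(3 * se, 1e-9), cls

    def test_unknown_class_rejected(self, diagnostic_freqs):
        fa, fb = diagnostic_freqs
        with pytest.raises(KeyError):
            hc.simulate_hybrid_class_frequency(fa, fb, "BxB1", 10, seed=1)


class TestPedigreeSimulator:
    @pytest.fixture()
    def founder_pools(self, diagnostic_freqs):
        fa, fb = diagnostic_freqs
        pa = hc.sample_population(fa, 30, seed=11, group_label="A")
        pb = hc.sample_population(fb, 30, seed=12, group_label="B")
        return pa, pb

    def test_f1_ancestry_exactly_half(self, founder_pools):
        pa, pb = founder_pools
        _, frac = hc.simulate_hybrid_class_pedigree(pa, pb, "F1", 50, seed=13)
        assert np.all(frac == 0.5)

    def test_bxa1_mean_ancestry(self, founder_pools):
        pa, pb = founder_pools
        _, frac = hc.simulate_hybrid_class_pedigree(pa, pb, "BxA1", 400, seed=14)
        se = frac.std() / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.75) <= 3 * se + 1e-9

    def test_pedigree_ancestry_variance_at_least_frequency_variance(
        self, founder_pools, diagnostic_freqs
    ):
        """BxA2 realized ancestry has positive spread, and the pedigree
        simulator's spread is never below the frequency method's (they
        coincide when parent chains are instantiated independently)."""
        pa, pb = founder_pools
        fa, fb = diagnostic_freqs
        _, frac_ped = hc.simulate_hybrid_class_pedigree(pa, pb, "BxA2", 500, seed=15)
        ds_freq = hc.simulate_hybrid_class_frequency(fa, fb, "BxA2", 500, seed=16)
        frac_freq = np.array(
            [np.mean([a == 101 for g in ind.genotype for a in g]) for ind in ds_freq.individuals]
        )
        assert frac_ped.var() > 0
        # sampling tolerance: equality is the theoretical floor
        assert frac_ped.var() >= 0.8 * frac_freq.var()

    def test_simulators_agree_in_expectation(self, founder_pools, diagnostic_freqs):
        pa, pb = founder_pools
        fa, fb = diagnostic_freqs
        for cls in ("F1", "F2", "BxA1", "BxA2"):
            _, frac_ped = hc.simulate_hybrid_class_pedigree(pa, pb, cls, 400, seed=17)
            ds_freq = hc.simulate_hybrid_class_frequency(fa, fb, cls, 400, seed=18)
            frac_freq = np.mean(
                [a == 101 for ind in ds_freq.individuals for g in ind.genotype for a in g]
            )
            assert abs(frac_ped.mean() - frac_freq) < 0.05, cls


class TestStudyFixture:
    @pytest.fixture(scope="class")
    def fixture(self):
        return hc.make_study_fixture(hc.SimulationConfig(seed=31))

    def test_composition(self, fixture):
        ds = fixture.dataset
        assert ds.n_individuals == 181
        assert sum(1 for i in ds.individuals if i.group_label == "razor") == 33

    def test_f1_always_carries_donor_haplotype(self, fixture):
        truth = fixture.truth.set_index("id")
        for ind in fixture.dataset.individuals:
            if truth.loc[ind.id, "true_class"] == "F1":
                assert ind.mt_haplotype == "hapB"

    def test_pure_focal_carries_focal_haplotype(self, fixture):
        truth = fixture.truth.set_index("id")
        for ind in fixture.dataset.individuals:
            if truth.loc[ind.id, "true_class"] == "pureA":
                assert ind.mt_haplotype == "hapA"

    def test_haplotypes_differ_at_exactly_nine_sites(self, fixture):
        hap_a = fixture.haplotype_refs["hapA"]
        hap_b = fixture.haplotype_refs["hapB"]
        assert len(hap_a) == len(hap_b) == 311
        assert hc.pairwise_differences(hap_a, hap_b) == 9

    def test_files_roundtrip(self, fixture, tmp_path):
        fixture.to_files(tmp_path)
        ds = hc.read_genepop(tmp_path / "genotypes.gen")
        ds = hc.apply_metadata(ds, hc.read_metadata(tmp_path / "metadata.tsv"))
        assert ds.n_individuals == fixture.dataset.n_individuals
        assert set(ds.group_labels) == set(fixture.dataset.group_labels)
        aln = hc.read_fasta_alignment(tmp_path / "haplotypes.fasta")
        assert "hapA" in aln.ids and "hapB" in aln.ids
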