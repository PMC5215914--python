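"""Genotype-frequency-class likelihoods, exact posterior, and the MCMC."""

import numpy as np
import pytest

import hybridcensus as hc
from hybridcensus.core import IndividualRecord, LocusDef, MicrosatDataset
from hybridcensus.hybridclass import DEFAULT_CLASSES, GenotypeClass

PA = {101: 1.0}
PB = {105: 1.0}


class TestLikelihood:
    def test_f1_forced_heterozygote(self):
        f1 = next(c for c in DEFAULT_CLASSES if c.name == "F1")
        assert hc.class_genotype_likelihood((101, 105), f1.phi, PA, PB) == 1.0

    def test_f2_homozygote_quarter(self):
        f2 = next(c for c in DEFAULT_CLASSES if c.name == "F2")
        assert hc.class_genotype_likelihood((101, 101), f2.phi, PA, PB) == 0.25

    def test_uninformative_locus_identical_across_classes(self):
        p = {101: 0.6, 103: 0.4}
        vals = {
            c.name: hc.class_genotype_likelihood((101, 103), c.phi, p, p)
            for c in DEFAULT_CLASSES
        }
        assert len(set(round(v, 12) for v in vals.values())) == 1

    def test_missing_genotype_is_neutral(self):
        f1 = next(c for c in DEFAULT_CLASSES if c.name == "F1")
        assert hc.class_genotype_likelihood(None, f1.phi, PA, PB) == 1.0

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            GenotypeClass("bad", (0.5, 0.2, 0.5))


def _single_locus_ds(genotype):
    return MicrosatDataset(
        [LocusDef("L1", (101, 105))], [IndividualRecord("x", "g", (genotype,))]
    )


def _freq_tables(pa=PA, pb=PB, loci=("L1",)):
    fa = hc.FreqTable(("A",), loci, {("A", l): pa for l in loci}, {("A", l): 100 for l in loci})
    fb = hc.FreqTable(("B",), loci, {("B", l): pb for l in loci}, {("B", l): 100 for l in loci})
    return fa, fb


class TestExactPosterior:
    def test_single_diagnostic_heterozygote(self):
        """Likelihoods (pureA, pureB, F1, F2, BxA, BxB) = (0, 0, 1, .5, .5, .5);
        uniform prior -> Q(F1) = 0.4, the three part-heterozygous classes 0.2."""
        fa, fb = _freq_tables()
        post = hc.exact_class_posterior(_single_locus_ds((101, 105)), DEFAULT_CLASSES, fa, fb)
        q = dict(zip(post.class_names, post.q[0]))
        assert q["F1"] == pytest.approx(0.4)
        for name in ("F2", "BxA", "BxB"):
            assert q[name] == pytest.approx(0.2)
        assert q["pureA"] == q["pureB"] == 0.0

    def test_uninformative_loci_posterior_equals_prior(self):
        p = {101: 0.5, 105: 0.5}
        fa, fb = _freq_tables(p, p)
        prior = np.array([0.3, 0.1, 0.2, 0.2, 0.1, 0.1])
        post = hc.exact_class_posterior(
            _single_locus_ds((101, 105)), DEFAULT_CLASSES, fa, fb, prior=prior
        )
        np.testing.assert_allclose(post.q[0], prior, atol=1e-12)

    def test_many_diagnostic_loci_confident_pure(self):
        loci = tuple(f"L{j}" for j in range(20))
        fa, fb = _freq_tables(loci=loci)
        ds = MicrosatDataset(
            [LocusDef(l, (101, 105)) for l in loci],
            [IndividualRecord("x", "g", tuple((101, 101) for _ in loci))],
        )
        post = hc.exact_class_posterior(ds, DEFAULT_CLASSES, fa, fb)
        q = dict(zip(post.class_names, post.q[0]))
        # pureA likelihood 1 vs BxA 0.5^20
        assert q["pureA"] > 0.99

    def test_zero_likelihood_everywhere_warns_uniform(self):
        fa, fb = _freq_tables()
        ds = _single_locus_ds((201, 201))  # allele unknown to both species
        with pytest.warns(UserWarning, match="zero likelihood"):
            post = hc.exact_class_posterior(ds, DEFAULT_CLASSES, fa, fb)
        np.testing.assert_allclose(post.q[0], 1 / 6, atol=1e-12)


def smoothed_frequencies(ds, group, prior="jeffreys"):
    """Posterior-mean allele frequencies for one group over the dataset's
    full allele universe (matching the MCMC's theta smoothing of alleles
    unseen in a species)."""
    sub = ds.group(group)
    counts = {}
    for j, locus in enumerate(ds.loci):
        c = {a: 0 for a in locus.observed_alleles}
        for ind in sub.individuals:
            g = ind.genotype[j]
            if g is not None:
                for al in g:
                    c[al] += 1
        n_alleles = len(locus.observed_alleles)
        pseudo = 1.0 / n_alleles if prior == "jeffreys" else 1.0
        total = sum(c.values()) + pseudo * n_alleles
        counts[(group, locus.name)] = {a: (k + pseudo) / total for a, k in c.items()}
    sizes = {(group, l.name): 1 for l in ds.loci}
    return hc.FreqTable((group,), ds.locus_names, counts, sizes)


def _mcmc_fixture(n_test=10, n_anchor=25, n_loci=10, seed=0):
    """Diagnostic-locus dataset: anchors of both species plus F1 test birds."""
    loci = [f"L{j}" for j in range(n_loci)]
    fa, fb = _freq_tables(loci=tuple(loci))
    a = hc.sample_population(fa, n_anchor, seed=seed + 1, group_label="A", id_prefix="a")
    b = hc.sample_population(fb, n_anchor, seed=seed + 2, group_label="B", id_prefix="b")
    f1 = hc.simulate_hybrid_class_frequency(fa, fb, "F1", n_test, seed=seed + 3, group_label="T")
    ds = a.concat(b).concat(f1)
    z = {ind.id: "pureA" for ind in a.individuals}
    z.update({ind.id: "pureB" for ind in b.individuals})
    return ds, z


class TestClassMcmc:
    def test_diagnostic_f1_confident(self):
        ds, z = _mcmc_fixture()
        cfg = hc.ClassModelConfig(iterations=4000, burnin=1000, seed=1)
        post = hc.run_class_mcmc(ds, cfg, z_fixed=z)
        q = post.to_frame()
        test_rows = q.loc[[i for i in q.index if i.startswith("F1")]]
        assert (test_rows["F1"] >= 0.99).all()

    def test_z_fixed_report_unit_posterior(self):
        ds, z = _mcmc_fixture(n_test=2, n_anchor=5, n_loci=3)
        cfg = hc.ClassModelConfig(iterations=1000, burnin=200, seed=2)
        post = hc.run_class_mcmc(ds, cfg, z_fixed=z)
        df = post.to_frame()
        for ind_id, cls in z.items():
            assert df.loc[ind_id, cls] == 1.0
            assert df.loc[ind_id, "z_fixed"]

    def test_q_rows_sum_to_one(self):
        ds, z = _mcmc_fixture(n_test=4, n_anchor=8, n_loci=4)
        post = hc.run_class_mcmc(
            ds, hc.ClassModelConfig(iterations=1500, burnin=300, seed=3), z_fixed=z
        )
        np.testing.assert_allclose(post.q.sum(axis=1), 1.0, atol=1e-9)

    def test_class_set_without_pures_rejected(self):
        ds, z = _mcmc_fixture(n_test=2, n_anchor=3, n_loci=2)
        classes = tuple(c for c in DEFAULT_CLASSES if c.name not in ("pureA",))
        cfg = hc.ClassModelConfig(classes=classes, iterations=500, burnin=100)
        with pytest.raises(ValueError, match="pure"):
            hc.run_class_mcmc(ds, cfg, z_fixed={})

    def test_replicate_stability(self):
        """Class calls do not change across replicate chains on clear data."""
        ds, z = _mcmc_fixture()
        calls = []
        for rep in range(3):
            post = hc.run_class_mcmc(
                ds,
                hc.ClassModelConfig(iterations=3000, burnin=600, seed=100 + rep),
                z_fixed=z,
            )
            calls.append(tuple(hc.classify_single_class(post)))
        assert calls[0] == calls[1] == calls[2]

    def test_mcmc_matches_exact_posterior_with_pinned_frequencies(self, study_conditions):
        """With many z-fixed parentals pinning theta, the MCMC marginals agree
        with the closed-form posterior computed at the parental sample
        frequencies (quick version; the acceptance suite runs it tighter)."""
        _, freq_a, freq_b = study_conditions
        a = hc.sample_population(freq_a, 150, seed=41, group_label="A", id_prefix="a")
        b = hc.sample_population(freq_b, 150, seed=42, group_label="B", id_prefix="b")
        test = hc.simulate_hybrid_class_frequency(freq_a, freq_b, "BxA1", 10, seed=43, group_label="T")
        ds = a.concat(b).concat(test)
        z = {i.id: "pureA" for i in a.individuals}
        z.update({i.id: "pureB" for i in b.individuals})
        post = hc.run_class_mcmc(
            ds,
            hc.ClassModelConfig(
                iterations=6000, burnin=1500, seed=44, fixed_pi=(1,) * 6
            ),
            z_fixed=z,
        )
        emp_a = smoothed_frequencies(ds, "A")
        emp_b = smoothed_frequencies(ds, "B")
        exact = hc.exact_class_posterior(test, DEFAULT_CLASSES, emp_a, emp_b)
        mcmc_rows = post.q[-10:]
        tv = 0.5 * np.abs(mcmc_rows - exact.q).sum(axis=1)
        assert tv.max() < 0.08

    def test_prior_washout_on_informative_data(self):
        """Jeffreys vs Uniform priors move Q by < 0.05 when data are strong."""
        ds, z = _mcmc_fixture(n_test=8, n_anchor=25, n_loci=10)
        results = []
        for pi, th in (("jeffreys", "jeffreys"), ("uniform", "uniform")):
            post = hc.run_class_mcmc(
                ds,
                hc.ClassModelConfig(
                    prior_pi=pi, prior_theta=th, iterations=4000, burnin=1000, seed=7
                ),
                z_fixed=z,
            )
            results.append(post.q[-8:])
        assert np.abs(results[0] - results[1]).max() < 0.05


class TestSingleClassRule:
    def _post(self, qrow, names=None):
        names = names or tuple(c.name for c in DEFAULT_CLASSES)
        return hc.ClassPosterior(("x",), names, np.array([qrow]), np.array([False]))

    def test_confident_call(self):
        q = [0.0, 0.0, 0.84, 0.1, 0.06, 0.0]
        assert hc.classify_single_class(self._post(q)).iloc[0] == "F1"

    def test_boundary_below_cutoff_unassigned(self):
        q = [0.69, 0.31, 0.0, 0.0, 0.0, 0.0]
        assert hc.classify_single_class(self._post(q)).iloc[0] == "unassigned"

    def test_uniform_unassigned(self):
        q = [1 / 6] * 6
        assert hc.classify_single_class(self._post(q)).iloc[0] == "unassigned"
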