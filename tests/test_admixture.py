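"""Admixture sampler, Evanno K selection, replicate alignment, thresholds."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

import hybridcensus as hc
from hybridcensus.core import IndividualRecord, LocusDef, MicrosatDataset

from conftest import make_diagnostic_freqs


def _diagnostic_two_pops(n=10, n_loci=8):
    fa, fb = make_diagnostic_freqs(n_loci=n_loci)
    a = hc.sample_population(fa, n, seed=1, group_label="A", id_prefix="a")
    b = hc.sample_population(fb, n, seed=2, group_label="B", id_prefix="b")
    return a.concat(b)


def exact_mean_q_by_enumeration(ds, alpha, lam, pinned_cluster):
    """Brute-force marginal posterior mean q on a tiny K=2 instance.

    Enumerates every assignment of free allele copies to clusters,
    integrating allele frequencies and admixture vectors analytically
    (Dirichlet-multinomial weights).  ``pinned_cluster`` maps individual
    index -> cluster for known-origin individuals (their copies are fixed).
    """
    codes, _ = ds.allele_matrix()
    n, n_loci, _ = codes.shape
    n_alleles = [len(l.observed_alleles) for l in ds.loci]
    free = [
        (i, l, c)
        for i in range(n)
        if i not in pinned_cluster
        for l in range(n_loci)
        for c in range(2)
    ]
    logws, eqs = [], []
    for assign in itertools.product(range(2), repeat=len(free)):
        z = np.zeros((n, n_loci, 2), dtype=int)
        for i, k in pinned_cluster.items():
            z[i] = k
        for (i, l, c), k in zip(free, assign):
            z[i, l, c] = k
        logw = 0.0
        for k in range(2):
            for l in range(n_loci):
                cnt = np.zeros(n_alleles[l])
                for i in range(n):
                    for c in range(2):
                        if z[i, l, c] == k:
                            cnt[codes[i, l, c]] += 1
                logw += gammaln(lam + cnt).sum() - gammaln(lam * n_alleles[l] + cnt.sum())
                logw -= n_alleles[l] * gammaln(lam) - gammaln(lam * n_alleles[l])
        eq = np.zeros((n, 2))
        for i in range(n):
            if i in pinned_cluster:
                eq[i, pinned_cluster[i]] = 1.0
                continue
            n_ik = np.array([(z[i] == k).sum() for k in range(2)], dtype=float)
            logw += (
                gammaln(2 * alpha)
                - gammaln(2 * n_loci + 2 * alpha)
                + (gammaln(alpha + n_ik) - gammaln(alpha)).sum()
            )
            eq[i] = (alpha + n_ik) / (2 * alpha + 2 * n_loci)
        logws.append(logw)
        eqs.append(eq)
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    w /= w.sum()
    return np.tensordot(w, np.array(eqs), axes=1)


class TestSampler:
    def test_diagnostic_populations_assigned_confidently(self):
        ds = _diagnostic_two_pops()
        cfg = hc.AdmixtureConfig(k=2, iterations=3000, burnin=500, seed=3)
        qm = hc.run_admixture(ds, cfg)
        assert np.all(qm.q.max(axis=1) >= 0.99)
        # the two groups land in different clusters
        groups = np.array(qm.groups)
        assert (
            qm.q[groups == "A"].argmax(axis=1).mean()
            != qm.q[groups == "B"].argmax(axis=1).mean()
        )

    def test_f1_between_fixed_populations_half_and_half(self, diagnostic_freqs):
        fa, fb = diagnostic_freqs
        ds = _diagnostic_two_pops(n=10, n_loci=14)
        f1 = hc.simulate_hybrid_class_frequency(fa, fb, "F1", 10, seed=4, group_label="H")
        qm = hc.run_admixture(
            ds.concat(f1), hc.AdmixtureConfig(k=2, iterations=4000, burnin=1000, seed=5)
        )
        groups = np.array(qm.groups)
        np.testing.assert_allclose(qm.q[groups == "H"], 0.5, atol=0.05)

    def test_q_rows_sum_to_one(self):
        ds = _diagnostic_two_pops(n=5, n_loci=3)
        qm = hc.run_admixture(ds, hc.AdmixtureConfig(k=3, iterations=1500, burnin=300, seed=6))
        np.testing.assert_allclose(qm.q.sum(axis=1), 1.0, atol=1e-9)

    def test_popinfo_requires_flagged_individuals(self):
        ds = _diagnostic_two_pops(n=3, n_loci=2)
        with pytest.raises(ValueError, match="known-origin"):
            hc.run_admixture(
                ds, hc.AdmixtureConfig(k=2, iterations=200, burnin=50, use_popinfo=True)
            )

    def test_flagged_groups_beyond_k_rejected(self):
        loci = [LocusDef("L1", ())]
        inds = [
            IndividualRecord(f"i{k}", f"g{k}", ((101, 101),), known_origin_flag=True)
            for k in range(3)
        ]
        ds = MicrosatDataset(loci, inds)
        with pytest.raises(ValueError, match="more than k"):
            hc.run_admixture(
                ds, hc.AdmixtureConfig(k=2, iterations=200, burnin=50, use_popinfo=True)
            )

    def test_sampler_matches_enumeration_quick(self):
        """Short-chain sanity check against the brute-force oracle (the
        tighter long-chain comparison lives in the acceptance suite)."""
        loci = [LocusDef("L1", (101, 103)), LocusDef("L2", (101, 103))]
        inds = [
            IndividualRecord("i0", "refA", ((101, 101), (101, 103)), known_origin_flag=True),
            IndividualRecord("i1", "q", ((101, 101), (101, 101))),
            IndividualRecord("i2", "q", ((103, 103), (103, 103))),
        ]
        ds = MicrosatDataset(loci, inds)
        exact = exact_mean_q_by_enumeration(ds, alpha=1.0, lam=1.0, pinned_cluster={0: 0})
        cfg = hc.AdmixtureConfig(
            k=2, iterations=30_000, burnin=5_000, sample_alpha=False, alpha=1.0,
            freq_model="independent", lambda_=1.0, use_popinfo=True, seed=8,
        )
        qm = hc.run_admixture(ds, cfg)
        assert np.abs(qm.q - exact).max() < 0.05


class TestRecoveryScaling:
    @staticmethod
    def _simulate_from_model(n_loci, rng):
        """Individuals drawn from the admixture model itself with known q."""
        q_true = rng.dirichlet((0.5, 0.5), size=40)
        loci = [LocusDef(f"L{j}", (101, 103, 105, 107)) for j in range(n_loci)]
        p = np.stack([rng.dirichlet((1, 1, 1, 1), size=n_loci) for _ in range(2)])
        alleles = np.array([101, 103, 105, 107])
        inds = []
        for i, q in enumerate(q_true):
            geno = []
            for l in range(n_loci):
                copies = []
                for _ in range(2):
                    k = rng.choice(2, p=q)
                    copies.append(int(alleles[rng.choice(4, p=p[k, l])]))
                geno.append(tuple(copies))
            inds.append(IndividualRecord(f"i{i}", "g", tuple(geno)))
        # two anchors per cluster to orient labels
        for k in range(2):
            geno = []
            for l in range(n_loci):
                a = alleles[rng.choice(4, p=p[k, l], size=2)]
                geno.append((int(a[0]), int(a[1])))
            inds.append(
                IndividualRecord(f"anchor{k}", f"ref{k}", tuple(geno), known_origin_flag=True)
            )
        return MicrosatDataset(loci, inds), q_true

    def test_rmse_decreases_with_locus_count(self):
        """Posterior mean q recovers the generating q better at 50 loci
        than at 14."""
        rng = np.random.default_rng(55)
        rmse = {}
        for n_loci in (14, 50):
            ds, q_true = self._simulate_from_model(n_loci, rng)
            qm = hc.run_admixture(
                ds,
                hc.AdmixtureConfig(
                    k=2, iterations=4000, burnin=1000, use_popinfo=True,
                    freq_model="independent", seed=56,
                ),
            )
            ref0 = qm.cluster_of_group("ref0")
            est = qm.q[:40, ref0]
            rmse[n_loci] = float(np.sqrt(np.mean((est - q_true[:, 0]) ** 2)))
        assert rmse[50] < rmse[14]


class TestEvanno:
    def test_second_difference_arithmetic(self):
        logliks = {
            k: [m + d for d in (-1.0, 0.0, 1.0)]
            for k, m in zip(range(1, 6), (-1000.0, -600.0, -590.0, -585.0, -584.0))
        }
        res = hc.select_K_evanno(logliks)
        assert res.best_k == 2
        # delta-K at K=2: |(-590) - 2*(-600) + (-1000)| / 1 = 390
        assert res.table.loc[2, "delta_K"] == pytest.approx(390.0)

    def test_no_interior_k_rejected(self):
        with pytest.raises(ValueError):
            hc.select_K_evanno({1: [-10.0, -11.0], 2: [-9.0, -9.5]})

    def test_zero_variance_rejected(self):
        logliks = {1: [-10.0] * 3, 2: [-9.0] * 3, 3: [-8.0] * 3}
        with pytest.raises(ValueError, match="variance"):
            hc.select_K_evanno(logliks)

    def test_two_population_fixture_selects_k2(self, study_conditions):
        """A clearly two-cluster sample maximizes delta-K at K = 2."""
        _, freq_a, freq_b = study_conditions
        a = hc.sample_population(freq_a, 25, seed=21, group_label="A", id_prefix="a")
        b = hc.sample_population(freq_b, 25, seed=22, group_label="B", id_prefix="b")
        ds = a.concat(b)
        logliks = {}
        for k in (1, 2, 3, 4):
            vals = []
            for rep in range(3):
                qm = hc.run_admixture(
                    ds,
                    hc.AdmixtureConfig(
                        k=k, iterations=2500, burnin=500, seed=1000 * k + rep
                    ),
                )
                vals.append(qm.mean_loglik)
            logliks[k] = vals
        assert hc.select_K_evanno(logliks).best_k == 2


def _qmatrix(q, ids=None, groups=None, flagged=None, loglik=-1.0):
    n, k = q.shape
    return hc.QMatrix(
        ids=tuple(ids or [f"i{j}" for j in range(n)]),
        groups=tuple(groups or ["g"] * n),
        flagged=np.array(flagged if flagged is not None else [False] * n),
        q=q,
        mean_loglik=loglik,
        k=k,
    )


class TestAlignment:
    def test_column_swap_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet((2, 1), size=12)
        r1 = _qmatrix(base)
        r2 = _qmatrix(base[:, ::-1])
        mean = hc.align_replicates([r1, r2])
        np.testing.assert_allclose(mean.q, base, atol=1e-12)

    def test_identical_runs_mean_is_the_run(self):
        rng = np.random.default_rng(1)
        base = rng.dirichlet((1, 1, 1), size=9)
        runs = [_qmatrix(base.copy()) for _ in range(20)]
        mean = hc.align_replicates(runs)
        np.testing.assert_allclose(mean.q, base, atol=1e-12)

    def test_injected_permutations_with_noise_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.dirichlet((2, 1, 1), size=15)
        perms = [(0, 1, 2), (2, 0, 1), (1, 2, 0)]
        runs = []
        for p in perms:
            noisy = np.clip(base[:, p] + rng.normal(0, 0.003, base.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            runs.append(_qmatrix(noisy))
        mean = hc.align_replicates(runs)
        assert np.abs(mean.q - base).max() < 0.01

    def test_k_above_exhaustive_limit_rejected(self):
        q = np.full((4, 7), 1 / 7)
        with pytest.raises(ValueError, match="exhaustive"):
            hc.align_replicates([_qmatrix(q), _qmatrix(q)])


class TestThresholdRule:
    def _qm(self, values):
        n = len(values)
        q = np.column_stack([values, 1 - np.asarray(values)])
        return _qmatrix(
            q, groups=["focal"] * n, flagged=[True] * n
        )

    @pytest.mark.parametrize(
        "q, threshold, expected",
        [
            (0.995, 0.99, "pure"),
            (0.849, 0.98, "admixed"),
            (0.98, 0.98, "pure"),  # boundary counts as pure
        ],
    )
    def test_threshold_calls(self, q, threshold, expected):
        qm = self._qm([q])
        rule = hc.ClassificationRule(threshold=threshold, focal_group="focal")
        assert hc.classify_by_threshold(qm, rule).iloc[0] == expected

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            hc.ClassificationRule(threshold=0.4, focal_group="focal")
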