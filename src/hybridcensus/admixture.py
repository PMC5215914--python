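"""Bayesian admixture clustering of multilocus codominant genotypes.

A Gibbs sampler in the style of the classic model-based clustering of
Pritchard, Stephens & Donnelly: each allele copy carries a latent cluster
of origin Z, each cluster holds per-locus allele frequencies P, and each
individual an admixture vector q ~ Dirichlet(alpha).  Two allele-frequency
priors are available:

* ``independent``: P[k, l] ~ Dirichlet(lambda) independently per cluster;
* ``correlated`` (default): cluster frequencies are tied to a latent
  ancestral frequency vector through per-cluster drift parameters F,
  P[k, l] ~ Dirichlet(P_anc[l] * (1 - F_k) / F_k), which borrows strength
  across clusters and is the better model for recently diverged species.

``use_popinfo`` activates the prior-population-information mode: an
individual whose origin is declared known (the POPFLAG convention) has its
q pinned to its declared cluster and contributes all of its allele copies
to that cluster's frequency estimate, anchoring the clustering.

The module also provides the Evanno delta-K rule for choosing the number
of clusters, label alignment across replicate runs (the label-switching
problem), and threshold classification of individuals into pure/admixed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MicrosatDataset

__all__ = [
    "AdmixtureConfig",
    "QMatrix",
    "EvannoResult",
    "ClassificationRule",
    "run_admixture",
    "run_replicates",
    "select_K_evanno",
    "align_replicates",
    "classify_by_threshold",
]


@dataclass
class AdmixtureConfig:
    """Sampler settings.

    Defaults mirror common practice for microsatellite admixture analyses
    (correlated frequencies, sampled alpha, 1e6 iterations with 1e5
    burn-in); shorter chains are adequate for the moderate-sized problems
    this package targets and are used throughout the test suite.
    """

    k: int = 2
    iterations: int = 1_000_000
    burnin: int = 100_000
    thinning: int = 1
    alpha: float = 1.0
    sample_alpha: bool = True
    alpha_max: float = 10.0
    freq_model: str = "correlated"  # or "independent"
    lambda_: float = 1.0
    use_popinfo: bool = False
    freqs_from_flagged_only: bool = False
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.freq_model not in ("correlated", "independent"):
            raise ValueError("freq_model must be 'correlated' or 'independent'")


@dataclass
class QMatrix:
    """Posterior-mean admixture proportions for one run (or aligned runs)."""

    ids: tuple[str, ...]
    groups: tuple[str, ...]
    flagged: np.ndarray  # bool, per individual
    q: np.ndarray  # (N, K), rows sum to 1
    mean_loglik: float
    k: int
    warnings: list[str] = field(default_factory=list)
    mean_alpha: float = float("nan")
    mean_drift: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.q, index=list(self.ids),
            columns=[f"cluster{c}" for c in range(self.k)],
        )
        df.insert(0, "group", list(self.groups))
        return df

    def cluster_of_group(self, group: str, flagged_only: bool = True) -> int:
        """The cluster with maximal mean q among (flagged) members of ``group``."""
        mask = np.array([g == group for g in self.groups])
        if flagged_only:
            mask &= self.flagged
        if not mask.any():
            mask = np.array([g == group for g in self.groups])
        if not mask.any():
            raise KeyError(f"no individuals in group {group!r}")
        return int(np.argmax(self.q[mask].mean(axis=0)))


def _pinned_clusters(ds: MicrosatDataset, k: int) -> np.ndarray:
    """Cluster index per individual (-1 = free) from known-origin flags.

    Flagged groups are mapped to clusters in order of first appearance.
    """
    pin = np.full(ds.n_individuals, -1, dtype=np.int64)
    group_to_cluster: dict[str, int] = {}
    for i, ind in enumerate(ds.individuals):
        if not ind.known_origin_flag:
            continue
        g = ind.group_label
        if g not in group_to_cluster:
            if len(group_to_cluster) >= k:
                raise ValueError(
                    f"flagged individuals declare more than k={k} groups"
                )
            group_to_cluster[g] = len(group_to_cluster)
        pin[i] = group_to_cluster[g]
    return pin


def _log_dirichlet(x: np.ndarray, conc: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise log Dirichlet density over the last axis, restricted to mask.

    Entries outside the mask must be zero in ``x`` and are ignored.
    """
    safe_x = np.where(mask & (x > 0), x, 1.0)
    safe_c = np.where(mask, conc, 1.0)
    term = np.where(mask, (safe_c - 1) * np.log(safe_x) - gammaln(safe_c), 0.0)
    return gammaln(np.where(mask, conc, 0.0).sum(axis=-1)) + term.sum(axis=-1)


def run_admixture(ds: MicrosatDataset, cfg: AdmixtureConfig) -> QMatrix:
    """Run the admixture Gibbs sampler and return posterior-mean q.

    Missing genotypes are skipped in all counts and likelihoods.  A crude
    convergence heuristic compares per-individual mean q between the first
    and second halves of the post-burn-in chain; discrepancies above 0.1
    are reported as warnings on the result, not errors.
    """
    if ds.n_individuals == 0:
        raise ValueError("empty dataset")
    k = cfg.k
    codes, _ = ds.allele_matrix()
    n, n_loci, _ = codes.shape
    n_alleles = np.array([len(l.observed_alleles) for l in ds.loci])
    a_max = int(n_alleles.max())
    valid = codes[:, :, 0] >= 0  # (N, L); both copies share missingness
    valid2 = np.repeat(valid[:, :, None], 2, axis=2)
    g = np.where(codes >= 0, codes, 0)

    pin = _pinned_clusters(ds, k) if cfg.use_popinfo else np.full(n, -1, dtype=np.int64)
    if cfg.use_popinfo and not (pin >= 0).any():
        raise ValueError("use_popinfo requires at least one known-origin individual")
    pinned = pin >= 0
    free = ~pinned

    rng = np.random.default_rng(cfg.seed)
    allele_mask = np.arange(a_max)[None, :] < n_alleles[:, None]  # (L, Amax)

    # empirical overall frequencies for initialization and the ancestral vector
    emp = np.zeros((n_loci, a_max))
    for j in range(n_loci):
        obs = codes[:, j, :][valid[:, j]]
        if obs.size:
            cnt = np.bincount(obs.ravel(), minlength=a_max)
            emp[j] = (cnt + 0.5) / (obs.size + 0.5 * n_alleles[j])
    emp = np.where(allele_mask, emp, 0.0)
    emp = emp / np.maximum(emp.sum(axis=1, keepdims=True), 1e-300)

    p = np.clip(emp[None, :, :] * (1 + 0.05 * rng.standard_normal((k, n_loci, a_max))), 1e-6, None)
    p = np.where(allele_mask[None], p, 0.0)
    p /= np.maximum(p.sum(axis=2, keepdims=True), 1e-300)
    p_anc = emp.copy()
    drift = np.full(k, 0.05)
    alpha = cfg.alpha

    q = np.full((n, k), 1.0 / k)
    if pinned.any():
        q[pinned] = 0.0
        q[pinned, pin[pinned]] = 1.0

    l_idx = np.arange(n_loci)[None, :, None]
    flat_l = np.broadcast_to(np.arange(n_loci)[None, :, None], (n, n_loci, 2))
    if cfg.freqs_from_flagged_only:
        if not pinned.any():
            raise ValueError("freqs_from_flagged_only requires flagged individuals")
        p_contrib = valid2 & pinned[:, None, None]
    else:
        p_contrib = valid2

    q_sum = np.zeros((n, k))
    q_sum_first = np.zeros((n, k))
    alpha_sum = 0.0
    drift_sum = np.zeros(k)
    loglik_sum = 0.0
    n_kept = 0
    n_kept_first = 0
    half = cfg.burnin + (cfg.iterations - cfg.burnin) // 2
    prior_anc = np.where(allele_mask, cfg.lambda_, 0.0)

    for sweep in range(cfg.iterations):
        # --- latent origins Z ------------------------------------------------
        p_t = p.transpose(1, 2, 0)  # (L, Amax, K)
        w = p_t[l_idx, codes.clip(min=0)] * q[:, None, None, :]  # (N, L, 2, K)
        tot = w.sum(axis=-1)
        if k > 1:
            u = rng.random((n, n_loci, 2)) * tot
            z = (np.cumsum(w, axis=-1) < u[..., None]).sum(axis=-1)
            np.clip(z, 0, k - 1, out=z)
        else:
            z = np.zeros((n, n_loci, 2), dtype=np.int64)

        # --- admixture proportions q ----------------------------------------
        counts_q = np.zeros((n, k))
        for c in range(k):
            counts_q[:, c] = ((z == c) & valid2).sum(axis=(1, 2))
        q = rng.gamma(alpha + counts_q)
        q /= np.maximum(q.sum(axis=1, keepdims=True), 1e-300)
        np.clip(q, 1e-12, None, out=q)
        q /= q.sum(axis=1, keepdims=True)
        if pinned.any():
            q[pinned] = 1e-12
            q[pinned, pin[pinned]] = 1.0
            q[pinned] /= q[pinned].sum(axis=1, keepdims=True)

        # --- cluster allele frequencies P -----------------------------------
        flat = (z * n_loci + flat_l) * a_max + g
        counts_p = np.bincount(flat[p_contrib].ravel(), minlength=k * n_loci * a_max)
        counts_p = counts_p.reshape(k, n_loci, a_max).astype(float)
        if cfg.freq_model == "correlated":
            conc = p_anc[None] * ((1 - drift) / drift)[:, None, None]
        else:
            conc = np.full((k, n_loci, a_max), cfg.lambda_)
        shape = np.where(allele_mask[None], conc + counts_p, 0.0)
        p = rng.gamma(np.maximum(shape, 1e-12)) * (shape > 0)
        p = np.clip(p, 1e-300, None) * (shape > 0)
        p /= np.maximum(p.sum(axis=2, keepdims=True), 1e-300)

        if cfg.freq_model == "correlated":
            # --- ancestral frequencies: per-locus Metropolis step ------------
            conc_prop = 200.0
            cur_c = np.where(allele_mask, p_anc * conc_prop + 0.05, 0.0)
            prop = rng.gamma(np.maximum(cur_c, 1e-12)) * allele_mask
            prop = np.clip(prop, 1e-300, None) * allele_mask
            prop /= np.maximum(prop.sum(axis=1, keepdims=True), 1e-300)
            prop_c = np.where(allele_mask, prop * conc_prop + 0.05, 0.0)
            log_acc = (
                _log_dirichlet(prop, prior_anc, allele_mask)
                - _log_dirichlet(p_anc, prior_anc, allele_mask)
                + _log_dirichlet(p_anc, prop_c, allele_mask)
                - _log_dirichlet(prop, cur_c, allele_mask)
            )
            for c in range(k):
                ratio = (1 - drift[c]) / drift[c]
                log_acc += _log_dirichlet(p[c], prop * ratio, allele_mask)
                log_acc -= _log_dirichlet(p[c], p_anc * ratio, allele_mask)
            accept = np.log(rng.random(n_loci)) < log_acc
            p_anc = np.where(accept[:, None], prop, p_anc)

            # --- drift parameters F ------------------------------------------
            for c in range(k):
                f_new = drift[c] + 0.04 * rng.standard_normal()
                f_new = abs(f_new)
                f_new = 2 - f_new if f_new > 1 else f_new  # reflect into (0, 1)
                if not (1e-4 < f_new < 1 - 1e-4):
                    continue
                la = _log_dirichlet(p[c], p_anc * (1 - f_new) / f_new, allele_mask).sum()
                lb = _log_dirichlet(p[c], p_anc * (1 - drift[c]) / drift[c], allele_mask).sum()
                if math.log(rng.random()) < la - lb:
                    drift[c] = f_new

        # --- alpha (Metropolis, uniform prior on (0, alpha_max]) -------------
        if cfg.sample_alpha and k > 1 and free.any():
            a_new = alpha + 0.1 * rng.standard_normal()
            if 0 < a_new <= cfg.alpha_max:
                logq = np.log(q[free]).sum()
                nf = int(free.sum())
                def _ldir(a: float) -> float:
                    return nf * (gammaln(k * a) - k * gammaln(a))
                log_acc_a = _ldir(a_new) - _ldir(alpha) + (a_new - alpha) * logq
                if math.log(rng.random()) < log_acc_a:
                    alpha = a_new

        # --- bookkeeping ------------------------------------------------------
        if sweep >= cfg.burnin:
            q_sum += q
            n_kept += 1
            if sweep < half:
                q_sum_first += q
                n_kept_first += 1
            loglik_sum += float(np.log(np.maximum(tot[valid2], 1e-300)).sum())
            alpha_sum += alpha
            drift_sum += drift

    q_mean = q_sum / n_kept
    mean_ll = loglik_sum / n_kept
    warns: list[str] = []
    if n_kept_first > 0 and n_kept > n_kept_first:
        q_first = q_sum_first / n_kept_first
        q_second = (q_sum - q_sum_first) / (n_kept - n_kept_first)
        disc = np.abs(q_first - q_second).max()
        if disc > 0.1:
            msg = (
                f"possible non-convergence: first/second half mean-q discrepancy "
                f"{disc:.3f} > 0.1"
            )
            warnings.warn(msg)
            warns.append(msg)
    return QMatrix(
        ids=ds.ids,
        groups=tuple(ind.group_label for ind in ds.individuals),
        flagged=np.array([ind.known_origin_flag for ind in ds.individuals]),
        q=q_mean,
        mean_loglik=mean_ll,
        k=k,
        warnings=warns,
        mean_alpha=alpha_sum / n_kept,
        mean_drift=drift_sum / n_kept,
    )


def run_replicates(ds: MicrosatDataset, cfg: AdmixtureConfig) -> list[QMatrix]:
    """Run ``cfg.replicates`` independent chains with derived seeds."""
    out = []
    for r in range(cfg.replicates):
        rcfg = AdmixtureConfig(**{**cfg.__dict__, "seed": (cfg.seed + 1_000_003 * (r + 1)) % (2**31 - 1)})
        out.append(run_admixture(ds, rcfg))
    return out


@dataclass
class EvannoResult:
    """Delta-K table and the selected number of clusters."""

    table: pd.DataFrame  # index K; columns mean_L, sd_L, delta_K
    best_k: int


def select_K_evanno(logliks: Mapping[int, Sequence[float]]) -> EvannoResult:
    """Choose K by the Evanno delta-K rule.

    ``logliks`` maps K to the replicate mean log-likelihoods L(K) — either
    plain floats or :class:`QMatrix` results.  For each interior K,
    ``delta_K = |mean(L(K+1)) - 2 mean(L(K)) + mean(L(K-1))| / sd(L(K))``;
    the K with the largest delta_K wins.  Requires at least three
    consecutive K values and at least 3 replicates at interior Ks.
    """
    logliks = {
        k: [v.mean_loglik if isinstance(v, QMatrix) else float(v) for v in vals]
        for k, vals in logliks.items()
    }
    ks = sorted(logliks)
    if len(ks) < 3 or ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError("need at least 3 consecutive K values")
    means = {k: float(np.mean(logliks[k])) for k in ks}
    sds = {k: float(np.std(logliks[k], ddof=1)) if len(logliks[k]) > 1 else 0.0 for k in ks}
    rows = []
    best_k, best_dk = None, -np.inf
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            if len(logliks[k]) < 3:
                raise ValueError(f"K={k}: need >= 3 replicates for delta-K")
            if sds[k] == 0:
                raise ValueError(
                    f"K={k}: zero replicate variance; run more replicates or iterations"
                )
            dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
            if dk > best_dk:
                best_dk, best_k = dk, k
        rows.append({"K": k, "mean_L": means[k], "sd_L": sds[k], "delta_K": dk})
    table = pd.DataFrame(rows).set_index("K")
    return EvannoResult(table, int(best_k))


def _similarity(a: np.ndarray, b: np.ndarray) -> float:
    """1 - normalized Frobenius distance between two Q matrices."""
    n = a.shape[0]
    return 1.0 - float(np.linalg.norm(a - b)) / math.sqrt(2.0 * n)


def align_replicates(runs: Sequence[QMatrix], max_exhaustive_k: int = 6) -> QMatrix:
    """Align cluster labels across replicate runs and average them.

    Label switching makes cluster indices arbitrary per run.  Each run is
    permuted to maximize similarity (1 - normalized Frobenius distance)
    with the running consensus, with repeated refinement passes until the
    permutation assignment stabilizes — for well-separated replicates this
    attains the same optimum as an exhaustive joint search while staying
    tractable for many replicates.
    """
    if len(runs) < 1:
        raise ValueError("need at least one run")
    k = runs[0].k
    if k > max_exhaustive_k:
        raise ValueError(
            f"K={k} exceeds the exhaustive alignment limit {max_exhaustive_k}"
        )
    ids = runs[0].ids
    for r in runs[1:]:
        if r.ids != ids or r.k != k:
            raise ValueError("runs must cover the same individuals with equal K")
    perms = list(itertools.permutations(range(k)))
    mats = [r.q for r in runs]
    # initialize against the first run (the unaligned mean is a symmetric
    # fixed point), then refine against the evolving consensus
    chosen = [
        max(perms, key=lambda p: _similarity(m[:, p], mats[0])) for m in mats
    ]
    aligned = [m[:, chosen[i]] for i, m in enumerate(mats)]
    for _ in range(10):
        changed = False
        consensus = np.mean(aligned, axis=0)
        for i, m in enumerate(mats):
            best = max(perms, key=lambda p: _similarity(m[:, p], consensus))
            if best != chosen[i]:
                chosen[i] = best
                aligned[i] = m[:, best]
                changed = True
        if not changed:
            break
    mean_q = np.mean(aligned, axis=0)
    mean_q /= mean_q.sum(axis=1, keepdims=True)
    return QMatrix(
        ids=ids,
        groups=runs[0].groups,
        flagged=runs[0].flagged,
        q=mean_q,
        mean_loglik=float(np.mean([r.mean_loglik for r in runs])),
        k=k,
        warnings=sum((r.warnings for r in runs), []),
    )


@dataclass
class ClassificationRule:
    """Purity rule: an individual is pure iff q toward the focal cluster is
    at or above ``threshold`` (the boundary value itself counts as pure).

    The focal cluster is resolved as the cluster maximizing mean q among
    the known-origin individuals of ``focal_group``.
    """

    threshold: float
    focal_group: str

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold < 1.0):
            raise ValueError("threshold must be strictly between 0.5 and 1")


def classify_by_threshold(qmat: QMatrix, rule: ClassificationRule) -> pd.Series:
    """Classify every individual as 'pure' or 'admixed' under the rule."""
    focal = qmat.cluster_of_group(rule.focal_group)
    calls = np.where(qmat.q[:, focal] >= rule.threshold, "pure", "admixed")
    return pd.Series(calls, index=list(qmat.ids), name="call")
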