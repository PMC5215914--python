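"""Bayesian assignment of individuals to genotype-frequency classes.

Hybrid categories (pure parental, F1, F2, first-generation backcrosses)
are distinguishable not by admixture proportion alone but by the expected
proportions of loci carrying 0, 1 or 2 allele copies from each species:
each class has a triple ``phi = (phi_AA, phi_AB, phi_BB)``.  For example
an F1 is AB at every locus (0, 1, 0) while an F2 is (0.25, 0.5, 0.25).

Given per-species allele frequencies theta_A, theta_B, the genotype
likelihood at one locus under a class is the phi-mixture of the three
ancestry-pair laws; loci are independent.  The Gibbs sampler alternates
class memberships, latent per-locus ancestry-pair states, allele
attributions, allele frequencies and mixing proportions.  Individuals of
known category (the z-flag convention) never change class but contribute
their allele copies to the frequency estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FreqTable, MicrosatDataset

__all__ = [
    "GenotypeClass",
    "DEFAULT_CLASSES",
    "ClassModelConfig",
    "ClassPosterior",
    "class_genotype_likelihood",
    "exact_class_posterior",
    "run_class_mcmc",
    "classify_single_class",
]


@dataclass(frozen=True)
class GenotypeClass:
    """A genotype-frequency class with its expected ancestry-pair triple."""

    name: str
    phi: tuple[float, float, float]  # (AA, AB, BB)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.phi) or abs(sum(self.phi) - 1.0) > 1e-9:
            raise ValueError(f"class {self.name!r}: phi must be non-negative and sum to 1")


DEFAULT_CLASSES: tuple[GenotypeClass, ...] = (
    GenotypeClass("pureA", (1.0, 0.0, 0.0)),
    GenotypeClass("pureB", (0.0, 0.0, 1.0)),
    GenotypeClass("F1", (0.0, 1.0, 0.0)),
    GenotypeClass("F2", (0.25, 0.5, 0.25)),
    GenotypeClass("BxA", (0.5, 0.5, 0.0)),
    GenotypeClass("BxB", (0.0, 0.5, 0.5)),
)


@dataclass
class ClassModelConfig:
    """Run settings; priors are named, their Dirichlet parameterization being
    Uniform = Dir(1) and Jeffreys = Dir(1/2) for the class proportions pi,
    and Uniform = Dir(1), Jeffreys = Dir(1/n_alleles) per locus for the
    allele frequencies theta."""

    classes: tuple[GenotypeClass, ...] = DEFAULT_CLASSES
    prior_pi: str = "jeffreys"  # or "uniform"
    prior_theta: str = "jeffreys"
    iterations: int = 1_000_000
    burnin: int = 100_000
    replicates: int = 3
    seed: int = 0
    fixed_pi: Optional[tuple[float, ...]] = None  # fix mixing proportions (oracle mode)

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        for p in (self.prior_pi, self.prior_theta):
            if p not in ("jeffreys", "uniform"):
                raise ValueError("priors must be 'jeffreys' or 'uniform'")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names")


@dataclass
class ClassPosterior:
    """Per-individual posterior probabilities over genotype classes."""

    ids: tuple[str, ...]
    class_names: tuple[str, ...]
    q: np.ndarray  # (N, C) rows sum to 1
    z_fixed: np.ndarray  # bool per individual

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, index=list(self.ids), columns=list(self.class_names))
        df.insert(0, "z_fixed", self.z_fixed)
        return df


def class_genotype_likelihood(
    genotype: Optional[tuple[int, int]],
    phi: Sequence[float],
    p_a: Mapping[int, float],
    p_b: Mapping[int, float],
) -> float:
    """Single-locus genotype likelihood under one class.

    For a heterozygote (i, j):
    ``phi_AA * 2 pA_i pA_j + phi_AB * (pA_i pB_j + pA_j pB_i) + phi_BB * 2 pB_i pB_j``;
    for a homozygote (i, i):
    ``phi_AA * pA_i^2 + phi_AB * pA_i pB_i + phi_BB * pB_i^2``.
    A missing genotype contributes 1 (the locus is skipped).
    """
    if genotype is None:
        return 1.0
    x, y = genotype
    pax, pay = p_a.get(x, 0.0), p_a.get(y, 0.0)
    pbx, pby = p_b.get(x, 0.0), p_b.get(y, 0.0)
    if x == y:
        return phi[0] * pax * pax + phi[1] * pax * pbx + phi[2] * pbx * pbx
    return (
        phi[0] * 2 * pax * pay
        + phi[1] * (pax * pby + pay * pbx)
        + phi[2] * 2 * pbx * pby
    )


def exact_class_posterior(
    ds: MicrosatDataset,
    classes: Sequence[GenotypeClass],
    freq_a: FreqTable,
    freq_b: FreqTable,
    prior: Optional[Sequence[float]] = None,
) -> ClassPosterior:
    """Closed-form class posterior under fixed, known allele frequencies.

    With theta pinned, classes are independent across individuals and the
    posterior is simply prior x multilocus likelihood, normalized.  This
    is the oracle the MCMC is checked against.  If every class has zero
    likelihood for an individual (alleles absent from both frequency
    tables), a uniform posterior is reported with a warning.
    """
    ga, gb = freq_a.groups[0], freq_b.groups[0]
    c = len(classes)
    pr = np.full(c, 1.0 / c) if prior is None else np.asarray(prior, dtype=float)
    pr = pr / pr.sum()
    rows = np.zeros((ds.n_individuals, c))
    for i, ind in enumerate(ds.individuals):
        like = np.ones(c)
        for j, locus in enumerate(ds.locus_names):
            pa = freq_a.freq(ga, locus)
            pb = freq_b.freq(gb, locus)
            for ci, cl in enumerate(classes):
                like[ci] *= class_genotype_likelihood(ind.genotype[j], cl.phi, pa, pb)
        post = pr * like
        total = post.sum()
        if total <= 0:
            warnings.warn(f"individual {ind.id!r}: zero likelihood under every class")
            post = np.full(c, 1.0 / c)
        else:
            post = post / total
        rows[i] = post
    return ClassPosterior(
        ds.ids, tuple(cl.name for cl in classes), rows,
        np.zeros(ds.n_individuals, dtype=bool),
    )


def _theta_prior(kind: str, n_alleles: np.ndarray, a_max: int) -> np.ndarray:
    mask = np.arange(a_max)[None, :] < n_alleles[:, None]
    if kind == "uniform":
        return np.where(mask, 1.0, 0.0)
    return np.where(mask, 1.0 / n_alleles[:, None], 0.0)


def run_class_mcmc(
    ds: MicrosatDataset,
    cfg: ClassModelConfig,
    z_fixed: Optional[Mapping[str, str]] = None,
) -> ClassPosterior:
    """Gibbs sampler over classes, ancestry-pair states and allele frequencies.

    ``z_fixed`` maps individual ids to class names for individuals whose
    genotypic category is known a priori; they are never re-assigned but
    their allele copies feed the theta updates.  The class set must include
    both pure classes (phi = (1,0,0) and (0,0,1)), otherwise the two
    species' frequencies are not identifiable.
    """
    classes = cfg.classes
    names = [c.name for c in classes]
    phis = np.array([c.phi for c in classes])  # (C, 3)
    if not any(tuple(p) == (1.0, 0.0, 0.0) for p in phis) or not any(
        tuple(p) == (0.0, 0.0, 1.0) for p in phis
    ):
        raise ValueError("class set must include both pure classes (AA- and BB-fixed)")
    z_fixed = dict(z_fixed or {})
    for ind_id, cls in z_fixed.items():
        if cls not in names:
            raise ValueError(f"z-fixed individual {ind_id!r} declares unknown class {cls!r}")

    codes, _ = ds.allele_matrix()
    n, n_loci, _ = codes.shape
    n_alleles = np.array([len(l.observed_alleles) for l in ds.loci])
    a_max = int(n_alleles.max())
    valid = codes[:, :, 0] >= 0
    g = np.where(codes >= 0, codes, 0)
    hom = g[:, :, 0] == g[:, :, 1]
    n_classes = len(classes)

    fixed_class = np.full(n, -1, dtype=np.int64)
    for i, ind in enumerate(ds.individuals):
        if ind.id in z_fixed:
            fixed_class[i] = names.index(z_fixed[ind.id])
    is_fixed = fixed_class >= 0
    free = ~is_fixed

    rng = np.random.default_rng(cfg.seed)
    theta_prior = _theta_prior(cfg.prior_theta, n_alleles, a_max)  # (L, Amax)
    pi_prior = 1.0 if cfg.prior_pi == "uniform" else 0.5
    mask = theta_prior > 0

    def _draw_theta(counts: np.ndarray) -> np.ndarray:
        shape = np.where(mask, theta_prior + counts, 0.0)
        t = rng.gamma(np.maximum(shape, 1e-12)) * (shape > 0)
        t = np.clip(t, 1e-300, None) * (shape > 0)
        return t / np.maximum(t.sum(axis=1, keepdims=True), 1e-300)

    theta_a = _draw_theta(np.zeros((n_loci, a_max)))
    theta_b = _draw_theta(np.zeros((n_loci, a_max)))
    if cfg.fixed_pi is not None:
        if len(cfg.fixed_pi) != n_classes:
            raise ValueError("fixed_pi length must match the class set")
        pi_fixed = np.asarray(cfg.fixed_pi, dtype=float)
        pi = pi_fixed / pi_fixed.sum()
    else:
        pi = np.full(n_classes, 1.0 / n_classes)
    c_state = np.where(is_fixed, fixed_class, rng.integers(n_classes, size=n))

    l_idx = np.arange(n_loci)[None, :, None]
    q_sum = np.zeros((n, n_classes))
    n_kept = 0

    for sweep in range(cfg.iterations):
        # per-copy species frequencies at the observed alleles
        pa = theta_a[l_idx, g]  # (N, L, 2)
        pb = theta_b[l_idx, g]
        het_factor = np.where(hom, 1.0, 2.0)
        l_aa = het_factor * pa[:, :, 0] * pa[:, :, 1]
        l_bb = het_factor * pb[:, :, 0] * pb[:, :, 1]
        l_ab = np.where(
            hom,
            pa[:, :, 0] * pb[:, :, 0],
            pa[:, :, 0] * pb[:, :, 1] + pa[:, :, 1] * pb[:, :, 0],
        )
        lw = np.stack([l_aa, l_ab, l_bb], axis=2)  # (N, L, 3)
        lw[~valid] = 1.0

        # class memberships for free individuals
        m = lw @ phis.T  # (N, L, C)
        logm = np.log(np.maximum(m, 1e-300))
        loglik = logm.sum(axis=1)  # (N, C)
        logits = np.log(np.maximum(pi, 1e-300))[None, :] + loglik
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random((n, 1)) * 1.0
        draw = (probs.cumsum(axis=1) < u).sum(axis=1)
        np.clip(draw, 0, n_classes - 1, out=draw)
        c_state = np.where(is_fixed, fixed_class, draw)

        # ancestry-pair states given classes
        phi_c = phis[c_state]  # (N, 3)
        wp = phi_c[:, None, :] * lw  # (N, L, 3)
        tot = np.maximum(wp.sum(axis=2, keepdims=True), 1e-300)
        uw = rng.random((n, n_loci, 1)) * tot
        w_state = (wp.cumsum(axis=2) < uw).sum(axis=2)
        np.clip(w_state, 0, 2, out=w_state)

        # attribute allele copies to species: 0 = from A, 1 = from B
        s = np.empty((n, n_loci, 2), dtype=np.int64)
        s[w_state == 0] = 0
        s[w_state == 2] = 1
        ab = w_state == 1
        # AB state: homozygote contributes one copy to each species;
        # heterozygote orientation is sampled by relative likelihood.
        p_first_from_a = pa[:, :, 0] * pb[:, :, 1]
        p_second_from_a = pa[:, :, 1] * pb[:, :, 0]
        denom = np.maximum(p_first_from_a + p_second_from_a, 1e-300)
        first_a = rng.random((n, n_loci)) < p_first_from_a / denom
        ori = np.where(first_a[..., None], np.array([0, 1]), np.array([1, 0]))
        hom_ori = np.broadcast_to(np.array([0, 1]), (n, n_loci, 2))
        s_ab = np.where(hom[..., None], hom_ori, ori)
        s[ab] = s_ab[ab]

        # theta updates from attributed copies
        valid2 = np.repeat(valid[:, :, None], 2, axis=2)
        flat = np.broadcast_to(np.arange(n_loci)[None, :, None], (n, n_loci, 2)) * a_max + g
        to_a = valid2 & (s == 0)
        to_b = valid2 & (s == 1)
        counts_a = np.bincount(flat[to_a].ravel(), minlength=n_loci * a_max).reshape(n_loci, a_max)
        counts_b = np.bincount(flat[to_b].ravel(), minlength=n_loci * a_max).reshape(n_loci, a_max)
        theta_a = _draw_theta(counts_a.astype(float))
        theta_b = _draw_theta(counts_b.astype(float))

        # mixing proportions from free individuals (unless pinned)
        if cfg.fixed_pi is None:
            if free.any():
                cls_counts = np.bincount(c_state[free], minlength=n_classes).astype(float)
            else:
                cls_counts = np.zeros(n_classes)
            pi = rng.gamma(pi_prior + cls_counts)
            pi /= pi.sum()

        if sweep >= cfg.burnin:
            q_sum[np.arange(n), c_state] += 1.0
            n_kept += 1

    q = q_sum / n_kept
    q[is_fixed] = 0.0
    q[is_fixed, fixed_class[is_fixed]] = 1.0
    return ClassPosterior(ds.ids, tuple(names), q, is_fixed)


def classify_single_class(post: ClassPosterior, cutoff: float = 0.70) -> pd.Series:
    """Call the top class when its posterior reaches ``cutoff``, else 'unassigned'."""
    best = post.q.argmax(axis=1)
    best_p = post.q.max(axis=1)
    calls = [
        post.class_names[b] if p >= cutoff else "unassigned"
        for b, p in zip(best, best_p)
    ]
    return pd.Series(calls, index=list(post.ids), name="class_call")
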