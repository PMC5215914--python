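"""Differentiation statistics and ordination for two-group microsatellite data.

Implements the Weir & Cockerham variance-components FST estimator (theta),
a permutation log-likelihood G test of genotypic differentiation, and a
factorial correspondence analysis (FCA) of allele-dosage-coded multilocus
genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import MicrosatDataset

__all__ = ["DiffStats", "FcaResult", "weir_cockerham_fst", "gtest_permutation", "fca"]


@dataclass
class DiffStats:
    """FST and/or G-test results for a pair of groups.

    ``fst`` is the multilocus Weir-Cockerham theta: variance components are
    summed across loci and alleles before taking the ratio.  ``fst`` is
    ``None`` when every locus is monomorphic (the estimator is undefined).
    The permutation p-value uses the +1 correction, so it is never exactly
    zero: ``p = (#{perm G >= observed G} + 1) / (n_perm + 1)``.
    """

    fst: Optional[float] = None
    per_locus_fst: Optional[pd.Series] = None
    g_statistic: Optional[float] = None
    p_value: Optional[float] = None
    n_permutations: int = 0

    def p_formatted(self, resolution: float = 1e-3) -> str:
        """Study-style p formatting: below resolution prints as '< resolution'."""
        if self.p_value is None:
            return "NA"
        if self.p_value < resolution:
            return f"P < {resolution:g}"
        return f"P = {self.p_value:.4g}"


def _group_matrices(ds: MicrosatDataset, group_a: str, group_b: str):
    codes, index = ds.allele_matrix()
    labels = np.array([ind.group_label for ind in ds.individuals])
    in_a = labels == group_a
    in_b = labels == group_b
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError(f"both groups must be non-empty: {group_a!r}, {group_b!r}")
    return codes, index, in_a, in_b


def weir_cockerham_fst(ds: MicrosatDataset, group_a: str, group_b: str) -> DiffStats:
    """Weir-Cockerham theta between two groups.

    Per locus and allele, the among-population (a), among-individual (b)
    and within-individual (c) variance components are computed from sample
    sizes, allele frequencies and observed heterozygote frequencies;
    multilocus theta is ``sum(a) / sum(a + b + c)`` over all loci and
    alleles.  Individuals missing a locus are excluded at that locus.
    """
    codes, index, in_a, in_b = _group_matrices(ds, group_a, group_b)
    r = 2
    sum_a_tot = 0.0
    sum_abc_tot = 0.0
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(ds.loci):
        n_alleles = len(locus.observed_alleles)
        if n_alleles < 2:
            per_locus[locus.name] = np.nan
            continue
        g = codes[:, j, :]  # (N, 2)
        valid = g[:, 0] >= 0
        sums_a = 0.0
        sums_abc = 0.0
        ok = False
        n_i = np.array([np.sum(valid & in_a), np.sum(valid & in_b)], dtype=float)
        if np.any(n_i < 1):
            per_locus[locus.name] = np.nan
            continue
        n_bar = n_i.mean()
        n_total = n_i.sum()
        n_c = (n_total - (n_i**2).sum() / n_total) / (r - 1)
        for a_idx in range(n_alleles):
            dose = (g == a_idx).sum(axis=1)  # 0/1/2 copies per individual
            het = (dose == 1) & ((g[:, 0] >= 0))
            p_i = np.array(
                [
                    dose[valid & in_a].sum() / (2 * n_i[0]),
                    dose[valid & in_b].sum() / (2 * n_i[1]),
                ]
            )
            h_i = np.array(
                [
                    het[valid & in_a].sum() / n_i[0],
                    het[valid & in_b].sum() / n_i[1],
                ]
            )
            p_bar = (n_i * p_i).sum() / n_total
            if p_bar <= 0 or p_bar >= 1:
                continue
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / n_total
            if n_bar <= 1:
                continue
            a_comp = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b_comp = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c_comp = h_bar / 2
            sums_a += a_comp
            sums_abc += a_comp + b_comp + c_comp
            ok = True
        if ok and sums_abc != 0:
            per_locus[locus.name] = sums_a / sums_abc
            sum_a_tot += sums_a
            sum_abc_tot += sums_abc
        else:
            per_locus[locus.name] = np.nan
    if sum_abc_tot == 0:
        return DiffStats(fst=None, per_locus_fst=pd.Series(per_locus))
    return DiffStats(
        fst=sum_a_tot / sum_abc_tot, per_locus_fst=pd.Series(per_locus, name="fst")
    )


def _dosage_matrix(ds: MicrosatDataset) -> tuple[np.ndarray, np.ndarray]:
    """Allele-dosage coding: X[i, col] = copies of allele ``col`` in individual i.

    Columns concatenate per-locus allele sets; also returns the column ->
    locus index array.
    """
    codes, index = ds.allele_matrix()
    n = ds.n_individuals
    cols = []
    locus_of_col = []
    offset = 0
    widths = [len(l.observed_alleles) for l in ds.loci]
    total = sum(widths)
    X = np.zeros((n, total), dtype=float)
    for j, w in enumerate(widths):
        g = codes[:, j, :]
        for c in range(2):
            valid = g[:, c] >= 0
            X[np.nonzero(valid)[0], offset + g[valid, c]] += 1
        locus_of_col.extend([j] * w)
        offset += w
    return X, np.array(locus_of_col)


def gtest_permutation(
    ds: MicrosatDataset,
    group_a: str,
    group_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> DiffStats:
    """Permutation log-likelihood G test of allelic differentiation.

    The observed statistic is the allele x group G (2 * sum obs*ln(obs/exp))
    per locus, summed across loci; the null distribution is built by
    permuting whole individuals between the two groups, which preserves
    within-individual allele association.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
    codes, index, in_a, in_b = _group_matrices(ds, group_a, group_b)
    keep = in_a | in_b
    sub_ids = [ind.id for ind, k in zip(ds.individuals, keep) if k]
    sub = ds.subset(sub_ids)
    X, locus_of_col = _dosage_matrix(sub)
    labels_a = np.array([ind.group_label == group_a for ind in sub.individuals])
    n_sub = len(sub_ids)
    rng = np.random.default_rng(seed)

    col_tot = X.sum(axis=0)  # total copies of each allele
    locus_ids = np.unique(locus_of_col)
    # per-locus copies per group depend on missingness; compute from X rows
    locus_cols = [np.nonzero(locus_of_col == j)[0] for j in locus_ids]

    def g_stat(mask_a: np.ndarray) -> float:
        total = 0.0
        counts_a = X[mask_a].sum(axis=0)
        counts_b = col_tot - counts_a
        for cols in locus_cols:
            ca, cb = counts_a[cols], counts_b[cols]
            na, nb = ca.sum(), cb.sum()
            tot = na + nb
            if tot == 0 or na == 0 or nb == 0:
                continue
            col_sum = ca + cb
            with np.errstate(divide="ignore", invalid="ignore"):
                ea = col_sum * na / tot
                eb = col_sum * nb / tot
                ta = np.where(ca > 0, ca * np.log(ca / ea), 0.0)
                tb = np.where(cb > 0, cb * np.log(cb / eb), 0.0)
            total += 2 * (np.nansum(ta) + np.nansum(tb))
        return float(total)

    observed = g_stat(labels_a)
    n_a = int(labels_a.sum())
    count_ge = 0
    for _ in range(n_perm):
        perm = np.zeros(n_sub, dtype=bool)
        perm[rng.choice(n_sub, size=n_a, replace=False)] = True
        if g_stat(perm) >= observed - 1e-12:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return DiffStats(g_statistic=observed, p_value=p, n_permutations=n_perm)


@dataclass
class FcaResult:
    """Individual coordinates and inertia fractions from correspondence analysis."""

    coordinates: pd.DataFrame  # index: individual id; columns: axis1..k
    inertia_fraction: np.ndarray
    total_inertia: float


def fca(
    ds: MicrosatDataset,
    k_axes: int = 3,
    positive_group: Optional[str] = None,
) -> FcaResult:
    """Factorial correspondence analysis of allele-dosage genotype coding.

    Individuals are rows of a 0/1/2 allele-count table; standard
    correspondence analysis (SVD of the standardized residuals of the
    row/column-mass model) yields individual coordinates scaled by the
    singular values.  Missing loci simply contribute no counts, which
    lowers that row's mass.

    ``positive_group``: if given, each axis is sign-flipped so that this
    group's mean coordinate is non-negative (a deterministic orientation).
    """
    if ds.n_individuals < 3:
        raise ValueError("need at least 3 individuals for an ordination")
    X, _ = _dosage_matrix(ds)
    X = X[:, X.sum(axis=0) > 0]
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0):
        raise ValueError("individual with no genotyped locus")
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # numerical rank cutoff
    rank = int(np.sum(sv > 1e-10))
    if k_axes > rank:
        warnings.warn(f"k_axes={k_axes} exceeds rank {rank}; truncating")
        k_axes = rank
    coords = (U[:, :k_axes] * sv[:k_axes]) / np.sqrt(r)[:, None]
    if positive_group is not None:
        mask = np.array([ind.group_label == positive_group for ind in ds.individuals])
        if mask.any():
            signs = np.sign(coords[mask].mean(axis=0))
            signs[signs == 0] = 1.0
            coords = coords * signs
    total_inertia = float((sv**2).sum())
    frac = (sv[:k_axes] ** 2) / total_inertia if total_inertia > 0 else np.zeros(k_axes)
    df = pd.DataFrame(
        coords, index=list(ds.ids), columns=[f"axis{i + 1}" for i in range(k_axes)]
    )
    return FcaResult(df, frac, total_inertia)
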