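"""Synthetic genotype and haplotype generation for hybrid-detection studies.

The generator emulates the data structure of a two-species captive
hybridization problem: a genetically depauperate focal species A (a
bottlenecked lineage with 2-5 alleles per microsatellite locus), a diverse
donor species B (up to 14 alleles per locus), differentiation calibrated
to a target Weir-Cockerham FST (default 0.28), and hybrid classes F1, F2,
F3 and backcrosses toward A only.  Two hybrid simulators are provided:

* a *frequency* method that draws each allele of a genotype independently
  from a class-specific gamete pool (each pool a mixture of the two
  parental allele-frequency distributions), and
* a *pedigree* method that performs explicit Mendelian matings and tracks
  each individual's realized ancestry fraction and maternal lineage.

Under the frequency method a class is fully described by its two gamete
pools; the pool of a derived class is the equal mixture of its parents'
pools, so the B-weight of the backcross gamete halves each generation
(0.5, 0.25, 0.125, 0.0625) and F2/F3 share the same pools (the
allele-frequency view has no inter-generation variance).  The pedigree
method keeps that variance and is the truth source for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .core import FreqTable, IndividualRecord, LocusDef, MicrosatDataset
from .popstats import weir_cockerham_fst

__all__ = [
    "SimulationConfig",
    "HybridClass",
    "HYBRID_CLASSES",
    "StudyFixture",
    "make_parental_frequencies",
    "sample_population",
    "simulate_hybrid_class_frequency",
    "simulate_hybrid_class_pedigree",
    "make_study_fixture",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    ``alleles_per_locus_a``/``_b`` bound the number of alleles segregating
    per locus in the bottlenecked (A) and diverse (B) species;
    ``target_fst`` is the Weir-Cockerham differentiation the calibration
    loop aims for, verified by sampling ``calibration_n`` individuals per
    side.  ``seed`` is mandatory: every stochastic call derives from it.
    """

    n_loci: int = 14
    alleles_per_locus_a: tuple[int, int] = (2, 5)
    alleles_per_locus_b: tuple[int, int] = (2, 14)
    target_fst: float = 0.28
    fst_tolerance: float = 0.03
    n_per_class: int = 100
    seed: int = 0
    scheme: str = "frequency"  # or "pedigree"
    calibration_n: int = 50
    max_proposals: int = 60
    missing_rate: float = 0.0
    morphology_slope: float = 14.0
    morphology_midpoint: float = 0.22

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fst < 1.0):
            raise ValueError("target_fst must be in (0, 1)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.scheme not in ("frequency", "pedigree"):
            raise ValueError("scheme must be 'frequency' or 'pedigree'")


@dataclass(frozen=True)
class HybridClass:
    """A hybrid category: name, expected A-ancestry, and its gamete pools.

    Each pool is an (A-weight, B-weight) pair summing to 1; a genotype of
    the class draws one allele from each pool.  Backcrossing is toward A
    only (the B-side backcross never occurs in the emulated program).
    """

    name: str
    expected_a_ancestry: float
    pools: tuple[tuple[float, float], tuple[float, float]]


def _derive(parent_pools, pure_pool):
    """Gamete pool of (class x pureA) offspring: pureA pool + mean of class pools."""
    mean = tuple((parent_pools[0][i] + parent_pools[1][i]) / 2 for i in range(2))
    return (pure_pool, mean)


_A = (1.0, 0.0)
_B = (0.0, 1.0)
_H1 = (0.5, 0.5)
_BXA1 = _derive((_A, _B), _A)          # ((1,0), (0.5,0.5))
_BXA2 = _derive(_BXA1, _A)             # ((1,0), (0.75,0.25))
_BXA3 = _derive(_BXA2, _A)             # ((1,0), (0.875,0.125))
_BXA4 = _derive(_BXA3, _A)             # ((1,0), (0.9375,0.0625))

HYBRID_CLASSES: dict[str, HybridClass] = {
    "pureA": HybridClass("pureA", 1.0, (_A, _A)),
    "pureB": HybridClass("pureB", 0.0, (_B, _B)),
    "F1": HybridClass("F1", 0.5, (_A, _B)),
    "F2": HybridClass("F2", 0.5, (_H1, _H1)),
    "F3": HybridClass("F3", 0.5, (_H1, _H1)),
    "BxA1": HybridClass("BxA1", 0.75, _BXA1),
    "BxA2": HybridClass("BxA2", 0.875, _BXA2),
    "BxA3": HybridClass("BxA3", 0.9375, _BXA3),
    "BxA4": HybridClass("BxA4", 0.96875, _BXA4),
}

# explicit mating recipe for the pedigree simulator: (parent1, parent2)
_PEDIGREE: dict[str, tuple[str, str]] = {
    "F1": ("pureA", "pureB"),
    "F2": ("F1", "F1"),
    "F3": ("F2", "F2"),
    "BxA1": ("F1", "pureA"),
    "BxA2": ("BxA1", "pureA"),
    "BxA3": ("BxA2", "pureA"),
    "BxA4": ("BxA3", "pureA"),
}


def _freq_arrays(freqs: FreqTable, group: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per locus: (allele sizes, probabilities) for one group of a FreqTable."""
    out = []
    for locus in freqs.loci:
        f = freqs.freq(group, locus)
        alleles = np.array(sorted(f), dtype=np.int64)
        probs = np.array([f[a] for a in alleles], dtype=float)
        out.append((alleles, probs))
    return out


def _pair_freq_arrays(freq_a: FreqTable, freq_b: FreqTable):
    """Union-allele view of two single-group tables sharing loci.

    Returns per locus (alleles, pA, pB) with frequencies aligned on the
    union allele set.
    """
    if freq_a.loci != freq_b.loci:
        raise ValueError("frequency tables must share the same loci")
    ga, gb = freq_a.groups[0], freq_b.groups[0]
    out = []
    for locus in freq_a.loci:
        fa, fb = freq_a.freq(ga, locus), freq_b.freq(gb, locus)
        alleles = np.array(sorted(set(fa) | set(fb)), dtype=np.int64)
        pa = np.array([fa.get(int(a), 0.0) for a in alleles])
        pb = np.array([fb.get(int(a), 0.0) for a in alleles])
        out.append((alleles, pa, pb))
    return out


def _one_locus_frequencies(
    rng: np.random.Generator,
    divergence: float,
    range_a: tuple[int, int],
    range_b: tuple[int, int],
    max_tries: int = 400,
) -> tuple[dict[int, float], dict[int, float]]:
    """Draw one locus's parental frequencies under a founder-bottleneck model.

    The diverse species B holds many alleles, most of them absent from A;
    the bottlenecked species A (founded by a handful of birds) holds 2-5
    alleles at high frequency.  Most A alleles are shared with B — no
    locus is fully diagnostic — but a shared allele that is common in A
    is typically uncommon in B.  The ``divergence`` dial in (0, 1] mixes
    A's founder frequencies back toward B's conditional distribution on
    A's support; the calibration loop tunes it until the sampled
    Weir-Cockerham FST hits the target.  Rare alleles (< 2%) are pruned
    and the draw rejected until the per-species allele counts fall inside
    the configured ranges.
    """
    for _ in range(max_tries):
        m_b = int(np.clip(2 + rng.geometric(0.30), range_b[0], range_b[1]))
        pb = rng.dirichlet(np.full(m_b, 0.8))
        pb = np.where(pb < 0.02, 0.0, pb)
        if (pb > 0).sum() < max(2, range_b[0]):
            continue
        pb = pb / pb.sum()
        k_a = int(rng.integers(range_a[0], range_a[1] + 1))
        # the divergence dial controls how much of A's allele set is shared
        # with B and how rare the shared alleles are in B: full divergence
        # means one rare shared allele per locus (no locus is ever fully
        # diagnostic), low divergence means A is mostly a subset of B
        p_share = float(np.clip(1.05 - 0.8 * divergence, 0.2, 0.95))
        n_shared = max(1, int(rng.binomial(k_a, p_share)))
        n_shared = min(n_shared, int((pb > 0).sum()))
        rare_bias = 0.02 + 0.5 * (1.0 - divergence)
        weights = np.where(pb > 0, 1.0 / (pb + rare_bias) ** 3, 0.0)
        shared_idx = rng.choice(m_b, size=n_shared, replace=False, p=weights / weights.sum())
        n_private = k_a - n_shared
        pa_support = np.concatenate([shared_idx, m_b + np.arange(n_private)])
        pa_raw = rng.dirichlet(np.full(k_a, 1.2))
        # mix toward B's conditional frequencies on the shared part
        pb_full = np.concatenate([pb, np.zeros(n_private)])
        pb_on_support = np.maximum(pb_full[pa_support], 1e-4) * np.concatenate(
            [np.ones(n_shared), np.zeros(n_private)]
        )
        if pb_on_support.sum() > 0:
            pb_on_support = pb_on_support / pb_on_support.sum()
        pa = divergence * pa_raw + (1.0 - divergence) * pb_on_support
        pa = np.where(pa < 0.02, 0.0, pa)
        if pa.sum() == 0:
            continue
        pa = pa / pa.sum()
        ka_eff = int((pa > 0).sum())
        kb_eff = int((pb > 0).sum())
        if not (range_a[0] <= ka_eff <= range_a[1] and range_b[0] <= kb_eff <= range_b[1]):
            continue
        sizes = 100 + 2 * np.arange(m_b + n_private)
        fa = {
            int(sizes[pa_support[i]]): float(pa[i]) for i in range(k_a) if pa[i] > 0
        }
        fb = {int(sizes[j]): float(pb[j]) for j in range(m_b) if pb[j] > 0}
        if not set(fa) & set(fb):
            continue  # keep every locus non-diagnostic, as in real panels
        return fa, fb
    raise RuntimeError(
        "could not draw locus frequencies inside the allele-count ranges; "
        "widen alleles_per_locus ranges"
    )


def _build_tables(cfg: SimulationConfig, divergence: float, seed: int):
    rng = np.random.default_rng(seed)
    divergence = float(np.clip(divergence, 1e-3, 1.0))
    loci = [f"locus{j + 1:02d}" for j in range(cfg.n_loci)]
    freqs = {}
    sizes = {}
    for locus in loci:
        fa, fb = _one_locus_frequencies(
            rng, divergence, cfg.alleles_per_locus_a, cfg.alleles_per_locus_b
        )
        freqs[("A", locus)] = fa
        freqs[("B", locus)] = fb
        sizes[("A", locus)] = sizes[("B", locus)] = 1_000_000  # parametric, not sampled
    table = FreqTable(("A", "B"), loci, freqs, sizes)
    return table.single_group("A"), table.single_group("B")


def _realized_fst(cfg: SimulationConfig, freq_a: FreqTable, freq_b: FreqTable, seed: int) -> float:
    a = sample_population(freq_a, cfg.calibration_n, seed=seed, group_label="A", id_prefix="calA")
    b = sample_population(freq_b, cfg.calibration_n, seed=seed + 1, group_label="B", id_prefix="calB")
    stats = weir_cockerham_fst(a.concat(b), "A", "B")
    return stats.fst if stats.fst is not None else 0.0


def make_parental_frequencies(cfg: SimulationConfig) -> tuple[FreqTable, FreqTable]:
    """Generate two parental allele-frequency tables calibrated to a target FST.

    A seeded calibration loop scales the between-species drift until the
    Weir-Cockerham FST realized by sampling ``calibration_n`` individuals
    per side lands within ``fst_tolerance`` of ``target_fst``.  The search
    is a coarse grid followed by local refinement and is bounded by
    ``max_proposals`` evaluations; if the band cannot be reached the call
    raises with a suggestion to widen the allele-count ranges.
    """
    base = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1)
    grid = np.linspace(0.15, 1.0, 14)
    evals: list[tuple[float, float, int]] = []  # (|err|, scale, seed)
    n_eval = 0
    for k, scale in enumerate(grid):
        if n_eval >= cfg.max_proposals:
            break
        seed = int((base + 7919 * k) % (2**31 - 1))
        fa, fb = _build_tables(cfg, scale, seed)
        fst = _realized_fst(cfg, fa, fb, seed + 13)
        n_eval += 1
        evals.append((abs(fst - cfg.target_fst), scale, seed))
        if abs(fst - cfg.target_fst) <= cfg.fst_tolerance:
            return fa, fb
    # refine around the best grid point with jittered scales
    evals.sort()
    best_scale = evals[0][1]
    rng = np.random.default_rng(base + 1)
    while n_eval < cfg.max_proposals:
        scale = best_scale * float(rng.uniform(0.7, 1.4))
        seed = int(rng.integers(0, 2**31 - 1))
        fa, fb = _build_tables(cfg, scale, seed)
        fst = _realized_fst(cfg, fa, fb, seed + 13)
        n_eval += 1
        if abs(fst - cfg.target_fst) <= cfg.fst_tolerance:
            return fa, fb
    raise RuntimeError(
        f"could not reach FST {cfg.target_fst} +/- {cfg.fst_tolerance} in "
        f"{cfg.max_proposals} proposals; widen alleles_per_locus ranges"
    )


def sample_population(
    freqs: FreqTable,
    n: int,
    seed: int,
    group_label: str = "pop",
    id_prefix: Optional[str] = None,
    known_origin: bool = False,
    missing_rate: float = 0.0,
) -> MicrosatDataset:
    """Sample ``n`` diploid individuals under Hardy-Weinberg from one group's
    frequencies (two independent allele draws per locus)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(freqs.groups) != 1:
        raise ValueError("sample_population expects a single-group FreqTable")
    group = freqs.groups[0]
    rng = np.random.default_rng(seed)
    per_locus = _freq_arrays(freqs, group)
    prefix = id_prefix if id_prefix is not None else group_label
    individuals = []
    draws = []
    for alleles, probs in per_locus:
        idx = rng.choice(len(alleles), size=(n, 2), p=probs)
        draws.append(alleles[idx])
    miss = (
        rng.random((n, len(per_locus))) < missing_rate
        if missing_rate > 0
        else np.zeros((n, len(per_locus)), dtype=bool)
    )
    for i in range(n):
        geno = tuple(
            None if miss[i, j] else (int(draws[j][i, 0]), int(draws[j][i, 1]))
            for j in range(len(per_locus))
        )
        individuals.append(
            IndividualRecord(f"{prefix}_{i + 1:03d}", group_label, geno, known_origin_flag=known_origin)
        )
    loci = [LocusDef(name, ()) for name in freqs.loci]
    return MicrosatDataset(loci, individuals)


def simulate_hybrid_class_frequency(
    freq_a: FreqTable,
    freq_b: FreqTable,
    cls: str,
    n: int,
    seed: int,
    group_label: Optional[str] = None,
    id_prefix: Optional[str] = None,
) -> MicrosatDataset:
    """Simulate class genotypes by the gamete-pool frequency rule.

    Per locus, each of the two alleles is drawn independently from one of
    the class's gamete pools; a pool with weights (wA, wB) has allele
    distribution ``wA * pA + wB * pB``.
    """
    if cls not in HYBRID_CLASSES:
        raise KeyError(f"unknown hybrid class {cls!r}; known: {sorted(HYBRID_CLASSES)}")
    if n <= 0:
        raise ValueError("n must be positive")
    hc = HYBRID_CLASSES[cls]
    rng = np.random.default_rng(seed)
    label = group_label if group_label is not None else cls
    prefix = id_prefix if id_prefix is not None else cls
    pair = _pair_freq_arrays(freq_a, freq_b)
    copies = []
    for pool in hc.pools:
        locus_draws = []
        for alleles, pa, pb in pair:
            p = pool[0] * pa + pool[1] * pb
            p = p / p.sum()
            idx = rng.choice(len(alleles), size=n, p=p)
            locus_draws.append(alleles[idx])
        copies.append(np.stack(locus_draws, axis=1))  # (n, L)
    c1, c2 = copies
    individuals = []
    for i in range(n):
        geno = tuple((int(c1[i, j]), int(c2[i, j])) for j in range(c1.shape[1]))
        individuals.append(IndividualRecord(f"{prefix}_{i + 1:03d}", label, geno))
    loci = [LocusDef(name, ()) for name in freq_a.loci]
    return MicrosatDataset(loci, individuals)


class _PedigreeSampler:
    """Recursive Mendelian mating engine with allele-origin bookkeeping."""

    def __init__(self, parents_a: MicrosatDataset, parents_b: MicrosatDataset, rng: np.random.Generator):
        if parents_a.n_individuals == 0 or parents_b.n_individuals == 0:
            raise ValueError("parent pools must be non-empty")
        if parents_a.locus_names != parents_b.locus_names:
            raise ValueError("parent datasets must share loci")
        self.rng = rng
        self.n_loci = parents_a.n_loci
        self.pool = {
            "pureA": self._as_arrays(parents_a, True),
            "pureB": self._as_arrays(parents_b, False),
        }

    @staticmethod
    def _as_arrays(ds: MicrosatDataset, from_a: bool):
        genos = []
        for ind in ds.individuals:
            g = np.array(
                [pair if pair is not None else (-1, -1) for pair in ind.genotype],
                dtype=np.int64,
            )
            genos.append(g)
        genos = np.stack(genos)  # (n, L, 2)
        origins = np.full(genos.shape, from_a, dtype=bool)
        return genos, origins

    def make(self, cls: str) -> tuple[np.ndarray, np.ndarray, str]:
        """One individual of ``cls``: (genotype (L,2), origin (L,2), maternal lineage)."""
        if cls == "pureA" or cls == "pureB":
            genos, origins = self.pool[cls]
            i = int(self.rng.integers(genos.shape[0]))
            return genos[i], origins[i], ("A" if cls == "pureA" else "B")
        if cls not in _PEDIGREE:
            raise KeyError(f"unknown hybrid class {cls!r}")
        p1, p2 = _PEDIGREE[cls]
        # the dam determines the maternal lineage: pure donor (B) parents are
        # always the dam (only donor females were used in crossings);
        # otherwise either parent may be the mother
        if p2 == "pureB" or (p1 != "pureB" and self.rng.random() < 0.5):
            p1, p2 = p2, p1
        g1, o1, mat1 = self.make(p1)
        g2, o2, _ = self.make(p2)
        pick1 = self.rng.integers(2, size=self.n_loci)
        pick2 = self.rng.integers(2, size=self.n_loci)
        ar = np.arange(self.n_loci)
        geno = np.stack([g1[ar, pick1], g2[ar, pick2]], axis=1)
        orig = np.stack([o1[ar, pick1], o2[ar, pick2]], axis=1)
        return geno, orig, mat1


def simulate_hybrid_class_pedigree(
    parents_a: MicrosatDataset,
    parents_b: MicrosatDataset,
    cls: str,
    n: int,
    seed: int,
    group_label: Optional[str] = None,
    id_prefix: Optional[str] = None,
) -> tuple[MicrosatDataset, np.ndarray]:
    """Simulate class genotypes by explicit Mendelian matings.

    Each individual is produced by recursively instantiating the class's
    mating recipe (e.g. BxA2 = BxA1 x pureA) from the given founder pools,
    sampling one allele per locus per gamete.  Returns the dataset and the
    realized A-ancestry fraction of each individual (the mean of per-locus
    allele origins), which the frequency simulator cannot provide.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if cls not in HYBRID_CLASSES:
        raise KeyError(f"unknown hybrid class {cls!r}")
    rng = np.random.default_rng(seed)
    sampler = _PedigreeSampler(parents_a, parents_b, rng)
    label = group_label if group_label is not None else cls
    prefix = id_prefix if id_prefix is not None else cls
    individuals = []
    fractions = np.empty(n)
    for i in range(n):
        geno, orig, maternal = sampler.make(cls)
        fractions[i] = orig.mean()
        pairs = tuple((int(a), int(b)) for a, b in geno)
        individuals.append(
            IndividualRecord(
                f"{prefix}_{i + 1:03d}", label, pairs,
                mt_haplotype=("hapA" if maternal == "A" else "hapB"),
            )
        )
    loci = [LocusDef(name, ()) for name in parents_a.loci]
    return MicrosatDataset(loci, individuals), fractions


# ---------------------------------------------------------------------------
# full study-shaped fixture
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))

_FIXTURE_CLASS_COUNTS = {
    "pureA": 66,
    "F1": 15,
    "F2": 12,
    "BxA1": 20,
    "BxA2": 20,
    "BxA3": 15,
}  # 148 candidate individuals, plus 33 known-origin B


@dataclass
class StudyFixture:
    """A complete synthetic study input: genotypes, metadata, haplotypes, truth."""

    dataset: MicrosatDataset
    freq_a: FreqTable
    freq_b: FreqTable
    haplotype_refs: dict[str, str]  # {"hapA": seq, "hapB": seq}, equal length
    sequences: dict[str, str]  # individual id -> its mtDNA sequence
    truth: "pd.DataFrame"  # id, true_class, true_b_ancestry

    def to_files(self, out_dir) -> None:
        """Write Genepop + metadata TSV + FASTA, format-identical to real inputs."""
        import os

        from .genepop import write_genepop, write_metadata

        os.makedirs(out_dir, exist_ok=True)
        write_genepop(self.dataset, os.path.join(out_dir, "genotypes.gen"))
        write_metadata(self.dataset, os.path.join(out_dir, "metadata.tsv"))
        with open(os.path.join(out_dir, "haplotypes.fasta"), "w", encoding="utf-8") as fh:
            for name, seq in self.haplotype_refs.items():
                fh.write(f">{name} reference\n{seq}\n")
            for ind_id, seq in self.sequences.items():
                fh.write(f">{ind_id}\n{seq}\n")
        self.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)


def _make_haplotype_pair(rng: np.random.Generator, length: int = 311, n_diff: int = 9):
    hap_a = _BASES[rng.integers(4, size=length)]
    hap_b = hap_a.copy()
    sites = rng.choice(length, size=n_diff, replace=False)
    for s in sites:
        choices = [b for b in "ACGT" if b != hap_a[s]]
        hap_b[s] = choices[int(rng.integers(3))]
    return "".join(hap_a), "".join(hap_b)


def make_study_fixture(
    cfg: SimulationConfig,
    class_counts: Optional[dict[str, int]] = None,
    n_known_b: int = 33,
) -> StudyFixture:
    """Build a study-shaped synthetic input.

    Composition mirrors the emulated program: ``n_known_b`` known-origin
    donor-species individuals (group ``razor``, all carrying hapB) plus a
    candidate population of pure-A and hybrid/backcross individuals
    (default 148).  Hybrids are produced by the pedigree simulator so that
    maternal lineage is tracked exactly: any descendant of a hybrid dam
    carries hapB, while backcrosses through pure-A dams carry hapA.
    Morphology labels are imperfect: the probability of a 'hybrid'
    morphology call is logistic in true B-ancestry, so lightly admixed
    birds often look pure.
    """
    import pandas as pd

    counts = dict(_FIXTURE_CLASS_COUNTS if class_counts is None else class_counts)
    rng = np.random.default_rng(cfg.seed)
    freq_a, freq_b = make_parental_frequencies(cfg)
    founders_a = sample_population(
        freq_a, 80, seed=int(rng.integers(2**31 - 1)), group_label="founderA"
    )
    founders_b = sample_population(
        freq_b, 80, seed=int(rng.integers(2**31 - 1)), group_label="founderB"
    )

    hap_a, hap_b = _make_haplotype_pair(rng)
    individuals: list[IndividualRecord] = []
    truth_rows = []
    sequences: dict[str, str] = {}

    razor = sample_population(
        freq_b, n_known_b, seed=int(rng.integers(2**31 - 1)),
        group_label="razor", id_prefix="razor", known_origin=True,
    )
    for ind in razor.individuals:
        rec = IndividualRecord(
            ind.id, "razor", ind.genotype, known_origin_flag=True,
            morphology_hybrid=False, mt_haplotype="hapB",
            sex=("male" if rng.random() < 0.5 else "female"),
        )
        individuals.append(rec)
        sequences[ind.id] = hap_b
        truth_rows.append({"id": ind.id, "true_class": "pureB", "true_b_ancestry": 1.0})

    for cls, n in counts.items():
        if n <= 0:
            continue
        if cls == "pureA":
            ds = sample_population(
                freq_a, n, seed=int(rng.integers(2**31 - 1)),
                group_label="candidate", id_prefix="pureA",
            )
            recs = list(ds.individuals)
            fractions = np.ones(n)
            maternal = ["hapA"] * n
        else:
            ds, fractions_a = simulate_hybrid_class_pedigree(
                founders_a, founders_b, cls, n,
                seed=int(rng.integers(2**31 - 1)), group_label="candidate", id_prefix=cls,
            )
            recs = list(ds.individuals)
            fractions = fractions_a
            maternal = [r.mt_haplotype for r in recs]
        for rec, frac_a, hap in zip(recs, fractions, maternal):
            b_anc = 1.0 - float(frac_a)
            p_hyb_morph = float(expit(cfg.morphology_slope * (b_anc - cfg.morphology_midpoint)))
            morph = bool(rng.random() < p_hyb_morph)
            group = "hybrid-phenotype" if morph else "alagoas-phenotype"
            year = int(rng.integers(1990, 2009))
            individuals.append(
                IndividualRecord(
                    rec.id, group, rec.genotype, known_origin_flag=False,
                    morphology_hybrid=morph, mt_haplotype=hap,
                    sex=("male" if rng.random() < 0.5 else "female"),
                    birth_year=year,
                )
            )
            sequences[rec.id] = hap_a if hap == "hapA" else hap_b
            truth_rows.append({"id": rec.id, "true_class": cls, "true_b_ancestry": b_anc})

    loci = [LocusDef(name, ()) for name in freq_a.loci]
    dataset = MicrosatDataset(loci, individuals)
    if cfg.missing_rate > 0:
        dataset = _inject_missing(dataset, cfg.missing_rate, int(rng.integers(2**31 - 1)))
    truth = pd.DataFrame(truth_rows)
    return StudyFixture(dataset, freq_a, freq_b, {"hapA": hap_a, "hapB": hap_b}, sequences, truth)


def _inject_missing(ds: MicrosatDataset, rate: float, seed: int) -> MicrosatDataset:
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    new = []
    for ind in ds.individuals:
        mask = rng.random(len(ind.genotype)) < rate
        geno = tuple(None if m else g for g, m in zip(ind.genotype, mask))
        new.append(replace(ind, genotype=geno))
    return MicrosatDataset(ds.loci, new, ds.missing_code)
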