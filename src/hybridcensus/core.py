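"""Core containers for multilocus codominant genotype data.

Everything downstream — simulation, admixture clustering, genotype-class
assignment, differentiation statistics — consumes the :class:`MicrosatDataset`
defined here: an ordered collection of diploid individuals typed at a shared
panel of microsatellite loci, with per-individual metadata (group label,
known-origin flag, morphology call, mtDNA haplotype, sex, birth year).

Genotypes are stored as unordered allele-size pairs ``(min, max)`` so that
heterozygote orientation never affects likelihoods or hashing; missing
genotypes are ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusDef",
    "IndividualRecord",
    "MicrosatDataset",
    "FreqTable",
    "AlleleSummary",
    "allele_frequencies",
    "summarize_alleles",
]

Genotype = Optional[tuple[int, int]]


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: a name and the allele sizes observed at it.

    Allele sizes are fragment lengths in base pairs; the collection is
    deduplicated, strictly positive, and sorted ascending.
    """

    name: str
    observed_alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        alleles = tuple(sorted(set(int(a) for a in self.observed_alleles)))
        if any(a <= 0 for a in alleles):
            raise ValueError(f"locus {self.name!r}: allele sizes must be positive")
        object.__setattr__(self, "observed_alleles", alleles)


@dataclass(frozen=True)
class IndividualRecord:
    """One diploid individual: id, metadata and its per-locus genotype.

    ``genotype`` holds one entry per locus of the parent dataset, in locus
    order: either an unordered allele pair (stored min,max) or ``None`` for
    missing.  ``known_origin_flag`` marks individuals whose population of
    origin is known a priori and may anchor allele-frequency estimation
    (the POPFLAG / z-flag convention of assignment software).
    """

    id: str
    group_label: str
    genotype: tuple[Genotype, ...]
    known_origin_flag: bool = False
    morphology_hybrid: bool = False
    mt_haplotype: Optional[str] = None
    sex: Optional[str] = None
    birth_year: Optional[int] = None

    def __post_init__(self) -> None:
        geno = tuple(
            None if g is None else (min(int(g[0]), int(g[1])), max(int(g[0]), int(g[1])))
            for g in self.genotype
        )
        object.__setattr__(self, "genotype", geno)
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"individual {self.id!r}: sex must be 'male' or 'female'")


class MicrosatDataset:
    """Individuals x loci diploid genotypes with group labels and metadata.

    Parameters
    ----------
    loci
        Ordered locus definitions.  Observed-allele sets are extended
        automatically to cover every allele present in the genotypes.
    individuals
        Ordered individual records; ids must be unique and every genotype
        must have exactly one entry per locus.
    missing_code
        The token representing a missing genotype in Genepop output
        (default ``"000000"``).
    """

    def __init__(
        self,
        loci: Sequence[LocusDef],
        individuals: Sequence[IndividualRecord],
        missing_code: str = "000000",
    ) -> None:
        individuals = tuple(individuals)
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        for ind in individuals:
            if len(ind.genotype) != len(loci):
                raise ValueError(
                    f"individual {ind.id!r}: {len(ind.genotype)} genotype entries "
                    f"for {len(loci)} loci"
                )
        # Extend each locus's observed alleles with what the genotypes carry.
        fixed = []
        for j, locus in enumerate(loci):
            seen = set(locus.observed_alleles)
            for ind in individuals:
                g = ind.genotype[j]
                if g is not None:
                    seen.update(g)
            fixed.append(LocusDef(locus.name, tuple(sorted(seen))))
        self.loci: tuple[LocusDef, ...] = tuple(fixed)
        self.individuals: tuple[IndividualRecord, ...] = individuals
        self.missing_code = missing_code

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.group_label, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.individuals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MicrosatDataset):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and self.missing_code == other.missing_code
        )

    def __repr__(self) -> str:
        return (
            f"<MicrosatDataset {self.n_individuals} individuals x {self.n_loci} loci, "
            f"groups={list(self.group_labels)}>"
        )

    # -- selection ----------------------------------------------------------

    def subset(self, ids: Iterable[str]) -> "MicrosatDataset":
        """Return the dataset restricted to the given ids (dataset order kept)."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"unknown individual ids: {sorted(missing)}")
        kept = [ind for ind in self.individuals if ind.id in wanted]
        return MicrosatDataset(self.loci, kept, self.missing_code)

    def group(self, label: str) -> "MicrosatDataset":
        """Return the dataset restricted to one group label."""
        kept = [ind for ind in self.individuals if ind.group_label == label]
        if not kept:
            raise KeyError(f"no individuals with group label {label!r}")
        return MicrosatDataset(self.loci, kept, self.missing_code)

    def relabel(self, mapping: Mapping[str, str]) -> "MicrosatDataset":
        """Return a copy with group labels translated through ``mapping``."""
        new = [
            replace(ind, group_label=mapping.get(ind.group_label, ind.group_label))
            for ind in self.individuals
        ]
        return MicrosatDataset(self.loci, new, self.missing_code)

    def concat(self, other: "MicrosatDataset") -> "MicrosatDataset":
        """Concatenate two datasets typed at the same loci (by name, in order)."""
        if self.locus_names != other.locus_names:
            raise ValueError("datasets are typed at different locus panels")
        return MicrosatDataset(
            self.loci, tuple(self.individuals) + tuple(other.individuals), self.missing_code
        )

    # -- numeric views ------------------------------------------------------

    def allele_matrix(self) -> tuple[np.ndarray, list[dict[int, int]]]:
        """Integer-coded genotype array.

        Returns
        -------
        codes : ndarray of shape (n_individuals, n_loci, 2)
            Per-locus allele indices into ``loci[j].observed_alleles``;
            missing copies are ``-1``.
        index : list of dict
            Per-locus mapping allele size -> column index.
        """
        index = [
            {a: k for k, a in enumerate(locus.observed_alleles)} for locus in self.loci
        ]
        codes = np.full((self.n_individuals, self.n_loci, 2), -1, dtype=np.int64)
        for i, ind in enumerate(self.individuals):
            for j, g in enumerate(ind.genotype):
                if g is not None:
                    codes[i, j, 0] = index[j][g[0]]
                    codes[i, j, 1] = index[j][g[1]]
        return codes, index

    def metadata_frame(self) -> pd.DataFrame:
        """Per-individual metadata as a DataFrame indexed by id."""
        rows = [
            {
                "id": ind.id,
                "group": ind.group_label,
                "known_origin": ind.known_origin_flag,
                "morphology_hybrid": ind.morphology_hybrid,
                "mt_haplotype": ind.mt_haplotype,
                "sex": ind.sex,
                "birth_year": ind.birth_year,
            }
            for ind in self.individuals
        ]
        return pd.DataFrame(rows).set_index("id")


class FreqTable:
    """Per-group, per-locus allele frequency distributions.

    Frequencies at each (group, locus) cell sum to 1 when the sample size
    (number of non-missing allele copies) is positive; an all-missing cell
    has an empty distribution and sample size 0.
    """

    def __init__(
        self,
        groups: Sequence[str],
        loci: Sequence[str],
        freqs: Mapping[tuple[str, str], Mapping[int, float]],
        sample_sizes: Mapping[tuple[str, str], int],
    ) -> None:
        self.groups = tuple(groups)
        self.loci = tuple(loci)
        self._freqs = {k: dict(v) for k, v in freqs.items()}
        self._n = dict(sample_sizes)
        for g in self.groups:
            for l in self.loci:
                n = self._n.get((g, l), 0)
                f = self._freqs.get((g, l), {})
                if n > 0:
                    total = sum(f.values())
                    if abs(total - 1.0) > 1e-9:
                        raise ValueError(
                            f"frequencies at ({g!r}, {l!r}) sum to {total}, not 1"
                        )
                if any(v < 0 for v in f.values()):
                    raise ValueError(f"negative frequency at ({g!r}, {l!r})")

    def freq(self, group: str, locus: str) -> dict[int, float]:
        """Allele size -> frequency at one (group, locus) cell (copy)."""
        return dict(self._freqs.get((group, locus), {}))

    def sample_size(self, group: str, locus: str) -> int:
        """Number of non-missing allele copies behind the cell."""
        return self._n.get((group, locus), 0)

    def alleles(self, locus: str) -> tuple[int, ...]:
        """Union of allele sizes seen at ``locus`` across all groups."""
        seen: set[int] = set()
        for g in self.groups:
            seen.update(self._freqs.get((g, locus), {}))
        return tuple(sorted(seen))

    def single_group(self, group: str) -> "FreqTable":
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return FreqTable(
            (group,),
            self.loci,
            {(group, l): self._freqs.get((group, l), {}) for l in self.loci},
            {(group, l): self._n.get((group, l), 0) for l in self.loci},
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame: group, locus, allele, freq, sample_size."""
        rows = []
        for g in self.groups:
            for l in self.loci:
                for a, f in sorted(self._freqs.get((g, l), {}).items()):
                    rows.append(
                        {"group": g, "locus": l, "allele": a, "freq": f,
                         "sample_size": self._n.get((g, l), 0)}
                    )
        return pd.DataFrame(rows, columns=["group", "locus", "allele", "freq", "sample_size"])


def allele_frequencies(
    ds: MicrosatDataset,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> FreqTable:
    """Tabulate allele frequencies per (group, locus).

    Parameters
    ----------
    ds
        The dataset.
    groups
        Optional explicit partition mapping group name -> individual ids.
        By default individuals are grouped by their ``group_label``.

    Frequencies are allele copies divided by non-missing copies; a cell
    where every genotype is missing gets an empty distribution with sample
    size 0 (not an error).
    """
    if groups is None:
        partition: dict[str, list[str]] = {}
        for ind in ds.individuals:
            partition.setdefault(ind.group_label, []).append(ind.id)
    else:
        partition = {g: list(ids) for g, ids in groups.items()}
        for g, ids in partition.items():
            if not ids:
                raise ValueError(f"group {g!r} is empty")
    by_id = {ind.id: ind for ind in ds.individuals}
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    sizes: dict[tuple[str, str], int] = {}
    for g, ids in partition.items():
        members = [by_id[i] for i in ids]
        for j, locus in enumerate(ds.loci):
            counts: dict[int, int] = {}
            for ind in members:
                geno = ind.genotype[j]
                if geno is not None:
                    for a in geno:
                        counts[a] = counts.get(a, 0) + 1
            n = sum(counts.values())
            sizes[(g, locus.name)] = n
            freqs[(g, locus.name)] = (
                {a: c / n for a, c in counts.items()} if n > 0 else {}
            )
    return FreqTable(tuple(partition), ds.locus_names, freqs, sizes)


@dataclass
class AlleleSummary:
    """Allele bookkeeping for two groups: counts, private alleles, diagnostics."""

    per_locus: pd.DataFrame  # locus, n_alleles_A, n_alleles_B, shared, diagnostic
    mean_alleles: dict[str, tuple[float, float]]  # group -> (mean, sd) across loci
    private_alleles: dict[str, list[tuple[str, int]]]  # group -> [(locus, allele)]
    diagnostic_loci: list[str]  # loci with no shared alleles

    @property
    def any_diagnostic(self) -> bool:
        return bool(self.diagnostic_loci)


def summarize_alleles(ds: MicrosatDataset, group_a: str, group_b: str) -> AlleleSummary:
    """Compare allelic composition of two disjoint groups.

    For each locus: alleles observed per group, whether the locus is fully
    diagnostic (no shared alleles among non-missing genotypes), and the
    private alleles of each group; plus the mean +/- sd allele count across
    loci per group.
    """
    ids_a = [i.id for i in ds.individuals if i.group_label == group_a]
    ids_b = [i.id for i in ds.individuals if i.group_label == group_b]
    if not ids_a or not ids_b:
        raise ValueError(f"both groups must be non-empty: {group_a!r}, {group_b!r}")
    ft = allele_frequencies(ds, {group_a: ids_a, group_b: ids_b})
    rows = []
    private: dict[str, list[tuple[str, int]]] = {group_a: [], group_b: []}
    diagnostic: list[str] = []
    counts_a, counts_b = [], []
    for locus in ds.locus_names:
        seen_a = set(ft.freq(group_a, locus))
        seen_b = set(ft.freq(group_b, locus))
        shared = seen_a & seen_b
        is_diag = bool(seen_a) and bool(seen_b) and not shared
        if is_diag:
            diagnostic.append(locus)
        for a in sorted(seen_a - seen_b):
            private[group_a].append((locus, a))
        for a in sorted(seen_b - seen_a):
            private[group_b].append((locus, a))
        counts_a.append(len(seen_a))
        counts_b.append(len(seen_b))
        rows.append(
            {
                "locus": locus,
                f"n_alleles_{group_a}": len(seen_a),
                f"n_alleles_{group_b}": len(seen_b),
                "n_shared": len(shared),
                "diagnostic": is_diag,
            }
        )
    means = {
        group_a: (float(np.mean(counts_a)), float(np.std(counts_a, ddof=1)) if len(counts_a) > 1 else math.nan),
        group_b: (float(np.mean(counts_b)), float(np.std(counts_b, ddof=1)) if len(counts_b) > 1 else math.nan),
    }
    return AlleleSummary(pd.DataFrame(rows), means, private, diagnostic)
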