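"""Maternal-lineage diagnosis from aligned mtDNA control-region haplotypes.

mtDNA is inherited through the maternal line only, so a donor-species
haplotype in an otherwise "pure-looking" individual reveals maternal-side
introgression arbitrarily many generations back — beyond the reach of a
moderate nuclear marker panel.  The tools here find fixed
species-diagnostic alignment positions between two reference lineages,
vote each query sequence into a lineage, and tabulate the haplotype
census per group.

Coordinates are 1-based alignment positions throughout, matching the
convention of published diagnostic-site tables.  Sequences are assumed
pre-aligned and of equal length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "HaplotypeAlignment",
    "DiagnosticSiteTable",
    "read_fasta_alignment",
    "find_diagnostic_sites",
    "assign_maternal_lineage",
    "haplotype_census",
    "pairwise_differences",
]

_MISSING = {"N", "-", "?"}


@dataclass
class HaplotypeAlignment:
    """Equal-length sequences over {A,C,G,T,N,-} with ids and group labels."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        object.__setattr__(
            self, "sequences", tuple(s.upper() for s in self.sequences)
        )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None


def read_fasta_alignment(
    path, groups: Optional[Mapping[str, str]] = None
) -> HaplotypeAlignment:
    """Read an aligned FASTA; ``groups`` optionally maps id -> group label."""
    ids, seqs, labels = [], [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        labels.append((groups or {}).get(rec.id, "unknown"))
    if not ids:
        raise ValueError(f"no sequences in {path!r}")
    return HaplotypeAlignment(tuple(ids), tuple(seqs), tuple(labels))


@dataclass
class DiagnosticSiteTable:
    """Fixed differences between two reference lineages.

    Rows are (1-based position, base fixed in lineage A, base fixed in
    lineage B); positions are strictly increasing.
    """

    sites: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        positions = [s[0] for s in self.sites]
        if positions != sorted(set(positions)):
            raise ValueError("positions must be strictly increasing")
        for pos, a, b in self.sites:
            if a == b:
                raise ValueError(f"position {pos}: bases must differ between lineages")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s[0] for s in self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sites, columns=["position", "base_lineageA", "base_lineageB"])


def _fixed_base(seqs: Sequence[str], pos0: int) -> Optional[str]:
    """The single non-missing base shared by all sequences at pos0, else None."""
    seen = {s[pos0] for s in seqs} - _MISSING
    return next(iter(seen)) if len(seen) == 1 else None


def find_diagnostic_sites(
    aln: HaplotypeAlignment,
    ref_a_ids: Iterable[str],
    ref_b_ids: Iterable[str],
) -> DiagnosticSiteTable:
    """Positions fixed within each reference set and different between them.

    A position qualifies iff every non-missing base is identical within
    each reference set and the two sets' bases differ; sites where either
    set is polymorphic are excluded even if the majority bases differ.
    """
    ref_a = [aln.sequence(i) for i in ref_a_ids]
    ref_b = [aln.sequence(i) for i in ref_b_ids]
    if not ref_a or not ref_b:
        raise ValueError("both reference sets must be non-empty")
    sites = []
    for pos0 in range(aln.length):
        base_a = _fixed_base(ref_a, pos0)
        base_b = _fixed_base(ref_b, pos0)
        if base_a is not None and base_b is not None and base_a != base_b:
            sites.append((pos0 + 1, base_a, base_b))
    return DiagnosticSiteTable(tuple(sites))


def assign_maternal_lineage(
    seq: str, sites: DiagnosticSiteTable
) -> tuple[str, float]:
    """Vote a sequence into a lineage by its diagnostic-site bases.

    Each site where the sequence carries lineage A's (or B's) base casts
    one vote; N or gap casts none.  Returns ``(lineage, match_fraction)``
    where lineage is ``"lineageA"``, ``"lineageB"`` or ``"ambiguous"``
    (tie or zero votes) and the fraction is winning votes / total sites.
    """
    seq = seq.upper()
    if len(sites) and len(seq) < sites.positions[-1]:
        raise ValueError("sequence shorter than the last diagnostic position")
    votes_a = votes_b = 0
    for pos, base_a, base_b in sites.sites:
        obs = seq[pos - 1]
        if obs in _MISSING:
            continue
        if obs == base_a:
            votes_a += 1
        elif obs == base_b:
            votes_b += 1
    total = len(sites) if len(sites) else 1
    if votes_a > votes_b:
        return "lineageA", votes_a / total
    if votes_b > votes_a:
        return "lineageB", votes_b / total
    return "ambiguous", 0.0


def pairwise_differences(seq1: str, seq2: str) -> int:
    """Number of positions with differing non-missing bases (alignment-wise)."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    return sum(
        1
        for a, b in zip(seq1.upper(), seq2.upper())
        if a != b and a not in _MISSING and b not in _MISSING
    )


def haplotype_census(
    assignments: Mapping[str, str],
    groups: Mapping[str, str],
    haplotypes: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Counts of individuals per (group, lineage), plus a pairwise-difference
    summary between the distinct haplotype sequences when provided.

    ``assignments`` maps individual id -> lineage call; ``groups`` maps
    id -> group label; ``haplotypes`` optionally maps haplotype name ->
    sequence.  With only two haplotypes a median-joining network is a
    single edge, so the difference matrix carries the same information.
    """
    rows = [
        {"id": i, "group": groups.get(i, "unknown"), "lineage": lin}
        for i, lin in assignments.items()
    ]
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["group", "lineage"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    diff = None
    if haplotypes:
        names = sorted(haplotypes)
        diff = pd.DataFrame(
            [
                [pairwise_differences(haplotypes[a], haplotypes[b]) for b in names]
                for a in names
            ],
            index=names,
            columns=names,
        )
    return counts, diff
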