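"""Genepop-dialect reader/writer and the metadata sidecar.

The dialect handled here is the common captive-population one: a title
line, locus names (one per line or comma-separated on one line), groups
delimited by ``POP`` lines, and per-individual rows ``id , g1 g2 ...``
where each genotype token concatenates two fixed-width allele sizes
(2- or 3-digit).  Missing genotypes are the all-zeros token (``000000``
for 3-digit files).

Genepop has no metadata channel, so per-individual attributes (group
name, morphology call, sex, birth year, mtDNA haplotype, known-origin
flag) travel in a sidecar TSV joined on individual id.
"""

from __future__ import annotations

import io
import os
from typing import Optional, TextIO, Union

import pandas as pd

from .core import IndividualRecord, LocusDef, MicrosatDataset

__all__ = ["read_genepop", "write_genepop", "read_metadata", "write_metadata", "apply_metadata"]

PathOrBuffer = Union[str, os.PathLike, TextIO]


class GenepopParseError(ValueError):
    """Raised when a Genepop file violates the expected layout."""


def _open_text(source: PathOrBuffer, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8"), True


def read_genepop(source: PathOrBuffer, digits: int = 3) -> MicrosatDataset:
    """Read a Genepop file into a :class:`MicrosatDataset`.

    Parameters
    ----------
    source
        Path or open text handle.
    digits
        Allele-size field width, 2 or 3.  The missing token is
        ``"0" * (2 * digits)``.

    Group labels are ``pop1``, ``pop2``, ... in POP-block order; use
    :func:`apply_metadata` to attach real labels from a sidecar table.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    missing_code = "0" * (2 * digits)
    handle, should_close = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if should_close:
            handle.close()
    if not lines:
        raise GenepopParseError("empty Genepop file")

    # Title, then locus names until the first POP line.
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            if "," in chunk:
                locus_names.extend(name.strip() for name in chunk.split(",") if name.strip())
            else:
                locus_names.append(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")
    if not locus_names:
        raise GenepopParseError("no locus names before first POP line")

    individuals: list[IndividualRecord] = []
    seen_ids: set[str] = set()
    pop_index = 0
    group = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_index += 1
            group = f"pop{pop_index}"
            continue
        if group is None:
            raise GenepopParseError(f"line {lineno + 1}: individual row before any POP line")
        if "," in line:
            ind_id, _, geno_part = line.partition(",")
            ind_id = ind_id.strip()
            tokens = geno_part.split()
        else:
            parts = line.split()
            ind_id, tokens = parts[0], parts[1:]
        if not ind_id:
            raise GenepopParseError(f"line {lineno + 1}: empty individual id")
        if ind_id in seen_ids:
            raise GenepopParseError(f"line {lineno + 1}: duplicate individual id {ind_id!r}")
        seen_ids.add(ind_id)
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(tokens)} genotype tokens for "
                f"{len(locus_names)} loci"
            )
        genotype = []
        for tok in tokens:
            if len(tok) != 2 * digits or not tok.isdigit():
                raise GenepopParseError(
                    f"line {lineno + 1}: malformed genotype token {tok!r} "
                    f"(expected {2 * digits} digits)"
                )
            if tok == missing_code:
                genotype.append(None)
            else:
                a1, a2 = int(tok[:digits]), int(tok[digits:])
                if a1 == 0 or a2 == 0:
                    # Half-missing genotypes are treated as missing outright.
                    genotype.append(None)
                else:
                    genotype.append((a1, a2))
        individuals.append(IndividualRecord(ind_id, group, tuple(genotype)))

    loci = [LocusDef(name, ()) for name in locus_names]
    return MicrosatDataset(loci, individuals, missing_code)


def write_genepop(
    ds: MicrosatDataset,
    target: Optional[PathOrBuffer] = None,
    digits: int = 3,
    title: str = "hybridcensus export",
) -> str:
    """Serialize a dataset to Genepop text (deterministic, byte-stable).

    POP blocks follow group order of first appearance.  Raises if any
    allele size does not fit in the chosen digit width.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits
    for locus in ds.loci:
        for a in locus.observed_alleles:
            if a >= limit:
                raise ValueError(
                    f"allele {a} at locus {locus.name!r} does not fit in {digits} digits"
                )
    missing_code = "0" * (2 * digits)
    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in ds.loci:
        buf.write(locus.name + "\n")
    for label in ds.group_labels:
        buf.write("POP\n")
        for ind in ds.individuals:
            if ind.group_label != label:
                continue
            tokens = []
            for g in ind.genotype:
                if g is None:
                    tokens.append(missing_code)
                else:
                    tokens.append(f"{g[0]:0{digits}d}{g[1]:0{digits}d}")
            buf.write(f"{ind.id} , " + " ".join(tokens) + "\n")
    text = buf.getvalue()
    if target is not None:
        handle, should_close = _open_text(target, "w")
        try:
            handle.write(text)
        finally:
            if should_close:
                handle.close()
    return text


METADATA_COLUMNS = ["id", "group", "known_origin", "morphology_hybrid", "sex", "birth_year", "mt_haplotype"]


def read_metadata(source: PathOrBuffer) -> pd.DataFrame:
    """Read the sidecar metadata TSV (columns ``id``, ``group``, ...)."""
    df = pd.read_csv(source, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("metadata table must have an 'id' column")
    return df.set_index("id")


def write_metadata(ds: MicrosatDataset, target: PathOrBuffer) -> None:
    """Write the dataset's metadata as a sidecar TSV."""
    df = ds.metadata_frame().reset_index()
    df.to_csv(target, sep="\t", index=False)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def apply_metadata(ds: MicrosatDataset, meta: pd.DataFrame) -> MicrosatDataset:
    """Attach sidecar metadata to a dataset, joined by individual id.

    Recognized columns: ``group``, ``known_origin``, ``morphology_hybrid``,
    ``sex``, ``birth_year``, ``mt_haplotype``.  Individuals absent from the
    table keep their current attributes.
    """
    new = []
    for ind in ds.individuals:
        if ind.id not in meta.index:
            new.append(ind)
            continue
        row = meta.loc[ind.id]
        kwargs = {}
        if "group" in meta.columns and pd.notna(row["group"]):
            kwargs["group_label"] = str(row["group"])
        if "known_origin" in meta.columns and pd.notna(row["known_origin"]):
            kwargs["known_origin_flag"] = _as_bool(row["known_origin"])
        if "morphology_hybrid" in meta.columns and pd.notna(row["morphology_hybrid"]):
            kwargs["morphology_hybrid"] = _as_bool(row["morphology_hybrid"])
        if "sex" in meta.columns and pd.notna(row["sex"]):
            kwargs["sex"] = str(row["sex"])
        if "birth_year" in meta.columns and pd.notna(row["birth_year"]):
            kwargs["birth_year"] = int(row["birth_year"])
        if "mt_haplotype" in meta.columns and pd.notna(row["mt_haplotype"]):
            kwargs["mt_haplotype"] = str(row["mt_haplotype"])
        from dataclasses import replace

        new.append(replace(ind, **kwargs))
    return MicrosatDataset(ds.loci, new, ds.missing_code)
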