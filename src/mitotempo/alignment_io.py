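"""Reading, validating, masking and partitioning mitogenome alignments.

Coordinates are 0-based half-open throughout (BED convention). Missing data
is any of ``N`` or ``-``; both are common in consensus sequences assembled
from degraded museum material.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN-")
MISSING_CHARS = frozenset("N-")

#: integer codes used by the numeric alignment view
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
CODE_BASES = np.array(list("ACGTN-"))
MISSING_CODE_MIN = 4  # codes >= this are missing


class AlignmentError(ValueError):
    """Sequences violate alignment invariants (unequal lengths etc.)."""


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class MetadataError(InputError):
    """Sample metadata does not resolve against the alignment."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of sequences over {A,C,G,T,N,-}.

    All sequences have identical length and ids are unique. Instances are
    immutable; masking/filtering operations return new alignments.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment must contain at least one sequence")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentError("alignment length must be > 0")
        bad = set("".join(self.seqs)) - VALID_CHARS
        if bad:
            raise InputError(f"invalid characters in sequences: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_codes(self) -> np.ndarray:
        """Return an (n, length) int8 matrix of base codes."""
        flat = np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int8)
        for b, c in BASE_CODES.items():
            lut[ord(b)] = c
        return lut[flat].reshape(self.n, self.length)

    def missing_fraction(self) -> np.ndarray:
        """Per-sequence fraction of missing (N or -) sites."""
        codes = self.to_codes()
        return (codes >= MISSING_CODE_MIN).mean(axis=1)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row subset in the given id order."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise InputError(f"ids not in alignment: {missing}")
        rows = [index[s] for s in ids]
        return Alignment(tuple(ids), tuple(self.seqs[i] for i in rows))

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def alignment_from_codes(ids: Sequence[str], codes: np.ndarray) -> Alignment:
    """Inverse of :meth:`Alignment.to_codes`."""
    seqs = ["".join(row) for row in CODE_BASES[codes]]
    return Alignment(tuple(ids), tuple(seqs))


@dataclass(frozen=True)
class MaskSet:
    """Non-overlapping 0-based half-open intervals on an alignment.

    Overlapping or book-ended input intervals are merged on construction.
    """

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise InputError(f"invalid interval ({start}, {end}): need 0 <= start < end")
        merged: list[list[int]] = []
        for start, end in sorted(self.intervals):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        object.__setattr__(self, "intervals", tuple((s, e) for s, e in merged))

    @property
    def total_width(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def column_mask(self, length: int) -> np.ndarray:
        """Boolean vector: True at masked columns. Errors when out of bounds."""
        mask = np.zeros(length, dtype=bool)
        for start, end in self.intervals:
            if end > length:
                raise InputError(f"interval ({start}, {end}) exceeds alignment length {length}")
            mask[start:end] = True
        return mask

    def complement(self, length: int) -> "MaskSet":
        """Intervals covering exactly the unmasked columns."""
        keep = ~self.column_mask(length)
        return MaskSet(_runs_to_intervals(keep))


def _runs_to_intervals(keep: np.ndarray) -> tuple[tuple[int, int], ...]:
    padded = np.concatenate([[False], keep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return tuple((int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2))


def read_alignment(fasta_path: str | Path) -> Alignment:
    """Read an aligned FASTA file; lowercase is normalized to uppercase."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {fasta_path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return Alignment(ids, seqs)


def read_bed(bed_path: str | Path) -> MaskSet:
    """Read a 3+ column BED file into a MaskSet (chromosome column ignored)."""
    intervals = []
    for line in Path(bed_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InputError(f"BED line has fewer than 3 columns: {line!r}")
        intervals.append((int(fields[1]), int(fields[2])))
    return MaskSet(tuple(intervals))


def apply_mask(aln: Alignment, mask: MaskSet) -> Alignment:
    """Delete masked columns (e.g. the hypervariable D-loop)."""
    keep = ~mask.column_mask(aln.length)
    if not keep.any():
        raise InputError("mask removes every column; alignment length must stay > 0")
    codes = aln.to_codes()[:, keep]
    return alignment_from_codes(aln.ids, codes)


def extract_region(aln: Alignment, intervals: MaskSet) -> Alignment:
    """Keep only the listed columns, concatenated in interval order.

    ``extract_region(aln, m.complement(L))`` equals ``apply_mask(aln, m)``.
    """
    cols: list[np.ndarray] = []
    for start, end in intervals.intervals:
        if end > aln.length:
            raise InputError(f"interval ({start}, {end}) exceeds alignment length {aln.length}")
        cols.append(np.arange(start, end))
    if not cols:
        raise InputError("no intervals to extract")
    codes = aln.to_codes()[:, np.concatenate(cols)]
    return alignment_from_codes(aln.ids, codes)


def filter_missing(
    aln: Alignment, max_missing_frac: float
) -> tuple[Alignment, list[str]]:
    """Drop sequences whose missing fraction strictly exceeds the threshold.

    Returns the filtered alignment and the list of dropped ids.
    """
    if not 0 <= max_missing_frac <= 1:
        raise InputError("max_missing_frac must lie in [0, 1]")
    frac = aln.missing_fraction()
    keep = frac <= max_missing_frac
    dropped = [sid for sid, k in zip(aln.ids, keep) if not k]
    if not keep.any():
        raise InputError("all sequences exceed the missing-data threshold")
    kept_ids = [sid for sid, k in zip(aln.ids, keep) if k]
    return aln.subset(kept_ids), dropped


REQUIRED_META_COLUMNS = ("id", "taxon", "era", "collection_year")


@dataclass
class SampleTable:
    """Per-sample metadata: taxon, era, collection year, optional geography.

    ``age_ybp`` is derived as ``reference_year - collection_year``.
    """

    df: pd.DataFrame
    reference_year: int = 2014

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.df.columns]
        if missing:
            raise MetadataError(f"metadata missing required columns: {missing}")
        if self.df["id"].duplicated().any():
            dupes = self.df.loc[self.df["id"].duplicated(), "id"].tolist()
            raise MetadataError(f"duplicate sample ids in metadata: {dupes}")
        bad_era = set(self.df["era"]) - {"historical", "modern"}
        if bad_era:
            raise MetadataError(f"unknown era values: {sorted(bad_era)}")
        self.df = self.df.copy()
        self.df["age_ybp"] = self.reference_year - self.df["collection_year"]
        if (self.df["age_ybp"] < 0).any():
            raise MetadataError("collection_year after reference year (age_ybp < 0)")

    def lookup(self, sample_id: str) -> pd.Series:
        row = self.df.loc[self.df["id"] == sample_id]
        if row.empty:
            raise MetadataError(f"sample id not in metadata: {sample_id}")
        return row.iloc[0]

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_sample_table(tsv_path: str | Path, reference_year: int = 2014) -> SampleTable:
    """Read tab-separated sample metadata (header required)."""
    df = pd.read_csv(tsv_path, sep="\t")
    return SampleTable(df, reference_year=reference_year)


def partition(
    aln: Alignment, table: SampleTable, keys: Sequence[str] = ("taxon", "era")
) -> dict[str, Alignment]:
    """Split the alignment into disjoint groups by metadata keys.

    Group labels join key values with ``/`` (e.g. ``grauer/historical``).
    Every alignment id must resolve in the table.
    """
    meta = table.df.set_index("id")
    missing = [sid for sid in aln.ids if sid not in meta.index]
    if missing:
        raise MetadataError(f"alignment ids missing from metadata: {missing}")
    groups: dict[str, list[str]] = {}
    for sid in aln.ids:
        label = "/".join(str(meta.loc[sid, k]) for k in keys)
        groups.setdefault(label, []).append(sid)
    return {label: aln.subset(ids) for label, ids in sorted(groups.items())}
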