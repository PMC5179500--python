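"""Readers and writers for the plain-text genomic formats used throughout.

Three containers travel through the pipeline: :class:`GenomicIntervalSet`
(BED 3-6 intervals: peaks, TSSs), :class:`CountTable` (genes x samples read
counts with sample metadata) and :class:`ContactMap` (per-chromosome sparse
symmetric bin-pair contact counts).

Conventions
-----------
* All coordinates are 0-based half-open (BED). The TSS of a ``+`` gene is its
  ``start``; of a ``-`` gene its ``end - 1``.
* A feature is assigned to the bin of its summit: ``floor(summit / bin_size)``.
  Peak summit = interval midpoint unless an explicit summit is carried; a TSS
  is a single base.
* Chromosome names are compared as exact strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomicIntervalSet",
    "CountTable",
    "ContactMap",
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_counts",
    "write_counts",
    "read_contacts",
    "write_contacts",
]

STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed input line; message names the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``score`` conventionally stores a peak's -log10 p-value.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def summit(self) -> int:
        """Midpoint base, used for bin assignment of peaks."""
        return (self.start + self.end) // 2

    @property
    def tss(self) -> int:
        """Single TSS base under the strand convention."""
        return self.start if self.strand != "-" else self.end - 1

    def bin(self, bin_size: int) -> int:
        return self.summit // bin_size


class GenomicIntervalSet:
    """An ordered collection of :class:`GenomicInterval`."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomicIntervalSet) and self.intervals == other.intervals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class SampleDescriptor:
    """Identity of one count column: library background/condition/replicate."""

    background: str  # e.g. WT, TKO, TKO+Elk1
    condition: str  # resting or TPA
    replicate: int
    read_class: str  # total or intronic

    def label(self) -> str:
        return f"{self.background}.{self.condition}.r{self.replicate}.{self.read_class}"

    @staticmethod
    def parse(label: str) -> "SampleDescriptor":
        parts = label.split(".")
        if len(parts) != 4 or not parts[2].startswith("r"):
            raise ParseError(f"cannot parse sample label {label!r}")
        return SampleDescriptor(parts[0], parts[1], int(parts[2][1:]), parts[3])


class CountTable:
    """Genes x samples matrix of non-negative integer read counts.

    The matrix is held as a pandas DataFrame indexed by gene id with one
    column per :class:`SampleDescriptor` label. Total and intronic read
    classes live side by side with identical gene order.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleDescriptor]):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        labels = [s.label() for s in samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample descriptors must be unique")
        if list(counts.columns) != labels:
            raise ValueError("count columns must match sample descriptor labels")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.samples = list(samples)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def select(self, read_class: str | None = None, background: str | None = None,
               condition: str | None = None) -> "CountTable":
        keep = [
            s
            for s in self.samples
            if (read_class is None or s.read_class == read_class)
            and (background is None or s.background == background)
            and (condition is None or s.condition == condition)
        ]
        return CountTable(self.counts[[s.label() for s in keep]], keep)

    def column(self, sample: SampleDescriptor | str) -> pd.Series:
        label = sample if isinstance(sample, str) else sample.label()
        if label not in self.counts.columns:
            raise KeyError(f"unknown sample {label!r}")
        return self.counts[label]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.samples == other.samples
            and self.counts.equals(other.counts)
        )


@dataclass
class ContactMap:
    """Per-chromosome symmetric sparse contact map at fixed bin width.

    Entries are canonical ``(i, j, count)`` with ``i <= j`` and ``count > 0``.
    """

    chrom: str
    bin_size: int
    bins_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bins_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_bins: int | None = None

    def __post_init__(self) -> None:
        self.bins_i = np.asarray(self.bins_i, dtype=np.int64)
        self.bins_j = np.asarray(self.bins_j, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.bins_i < 0).any() or (self.bins_j < 0).any():
            raise ValueError("bin indices must be >= 0")
        if (self.counts <= 0).any():
            raise ValueError("stored counts must be > 0")
        if (self.bins_i > self.bins_j).any():
            raise ValueError("entries must be canonical (i <= j)")
        if self.n_bins is None:
            self.n_bins = int(max(self.bins_j.max(initial=-1) + 1, 0))

    @classmethod
    def from_entries(cls, chrom: str, bin_size: int,
                     entries: Iterable[tuple[int, int, int]],
                     n_bins: int | None = None) -> "ContactMap":
        """Accumulate possibly duplicated / unordered (i, j, count) entries."""
        tuples = list(entries)
        if not tuples:
            return cls(chrom, bin_size, n_bins=n_bins)
        arr = np.asarray(tuples, dtype=np.int64)
        i = np.minimum(arr[:, 0], arr[:, 1])
        j = np.maximum(arr[:, 0], arr[:, 1])
        df = pd.DataFrame({"i": i, "j": j, "c": arr[:, 2]})
        agg = df.groupby(["i", "j"], sort=True)["c"].sum().reset_index()
        agg = agg[agg["c"] > 0]
        return cls(chrom, bin_size, agg["i"].to_numpy(), agg["j"].to_numpy(),
                   agg["c"].to_numpy(), n_bins=n_bins)

    def to_dense(self, n_bins: int | None = None) -> np.ndarray:
        n = n_bins if n_bins is not None else self.n_bins
        m = np.zeros((n, n), dtype=np.float64)
        m[self.bins_i, self.bins_j] = self.counts
        m[self.bins_j, self.bins_i] = self.counts
        return m

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContactMap)
            and self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and np.array_equal(self.bins_i, other.bins_i)
            and np.array_equal(self.bins_j, other.bins_j)
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path, format: str = "BED") -> GenomicIntervalSet:
    """Read a BED3-6 file into a :class:`GenomicIntervalSet`.

    Column 5 (``score``) is interpreted as a float (-log10 p for peaks).
    Raises :class:`ParseError` naming the line number on malformed input.
    """
    if format != "BED":
        raise ValueError(f"unsupported interval format {format!r}")
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return GenomicIntervalSet(intervals)


def write_intervals(intervals: GenomicIntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = repr(iv.score) if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts(path) -> CountTable:
    """Read a TSV count table (header = sample labels, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"non-numeric count in column {col!r}")
        if (vals < 0).any():
            raise ParseError(f"negative count in column {col!r}")
        if (vals % 1 != 0).any():
            raise ParseError(f"non-integer count in column {col!r}")
        df[col] = vals.astype(np.int64)
    samples = [SampleDescriptor.parse(c) for c in df.columns]
    return CountTable(df, samples)


def write_counts(table: CountTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def read_contacts(path, bin_size: int, mode: str = "pairs",
                  chrom: str | None = None) -> ContactMap:
    """Read intra-chromosomal contacts.

    ``mode="pairs"``: lines of ``chrom pos1 pos2`` read pairs; positions are
    assigned to bins by ``floor(pos / bin_size)`` and each line contributes one
    count. ``mode="triplets"``: lines of ``chrom bin_i bin_j count``.
    ``(i, j)`` and ``(j, i)`` accumulate into the same canonical entry.
    """
    if mode not in {"pairs", "triplets"}:
        raise ValueError(f"mode must be 'pairs' or 'triplets', got {mode!r}")
    entries: list[tuple[int, int, int]] = []
    seen_chrom = chrom
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            want = 3 if mode == "pairs" else 4
            if len(fields) < want:
                raise ParseError(f"line {lineno}: expected {want} columns")
            c = fields[0]
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise ParseError(
                    f"line {lineno}: chromosome {c!r} differs from {seen_chrom!r} "
                    "in intra-chromosomal mode"
                )
            try:
                a, b = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer fields") from exc
            if mode == "pairs":
                entries.append((a // bin_size, b // bin_size, 1))
            else:
                try:
                    n = int(fields[3])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: non-integer count") from exc
                entries.append((a, b, n))
    return ContactMap.from_entries(seen_chrom or "", bin_size, entries)


def write_contacts(cmap: ContactMap, path) -> None:
    """Write a contact map as 4-column triplet text (readable by triplet mode)."""
    with open(path, "w") as fh:
        for i, j, c in zip(cmap.bins_i, cmap.bins_j, cmap.counts):
            fh.write(f"{cmap.chrom}\t{i}\t{j}\t{c}\n")
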