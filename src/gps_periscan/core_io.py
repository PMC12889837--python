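"""Domain types and readers/writers for FASTA, BED, bedGraph and TSV, plus
half-open interval arithmetic shared by all pipeline stages.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only in human-readable report strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("gps_periscan")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")


class FormatError(ValueError):
    """Raised for malformed input files; message carries path and line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on one chromosome; 0 if they touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("distance between different chromosomes is undefined")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def report_str(self) -> str:
        """1-based inclusive rendering for human-readable reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}{'' if self.strand == '.' else '(' + self.strand + ')'}"


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence, stored upper-case."""

    identifier: str
    sequence: str
    mode: str = "nucleotide"  # nucleotide | protein

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"mode must be nucleotide or protein, got {self.mode!r}")
        alphabet = NUCLEOTIDE_ALPHABET if self.mode == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise ValueError(
                f"{self.identifier}: illegal {self.mode} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SignalTrack:
    """Sorted, non-overlapping (interval, fold-change value) records."""

    records: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r[0].chrom, r[0].start))
        prev: GenomicInterval | None = None
        for iv, value in self.records:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {iv.report_str()}")
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(
                    f"overlapping records {prev.report_str()} and {iv.report_str()}"
                )
            prev = iv

    def max_over(self, query: GenomicInterval) -> float:
        """Maximum signal over the query interval; 0 where the track is silent."""
        best = 0.0
        for iv, value in self.records:
            if iv.overlaps(query):
                best = max(best, value)
        return best

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv, _ in self.records:
            seen.setdefault(iv.chrom, None)
        return list(seen)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, mode: str = "nucleotide") -> list[SequenceRecord]:
    """Strict FASTA reader: one record per header, sequences upper-cased.

    Malformed headers, empty sequences and illegal characters raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0
    alphabet = NUCLEOTIDE_ALPHABET if mode == "nucleotide" else PROTEIN_ALPHABET

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has empty sequence")
        records.append(SequenceRecord(header, seq, mode))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                bad = set(line.upper()) - alphabet
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal {mode} characters {sorted(bad)}"
                    )
                chunks.append(line.upper())
    flush()
    logger.info("read_fasta: %s -> %d records", path, len(records))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 reader (0-based half-open); strand from column 6 when present."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(cols[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    logger.info("read_bed: %s -> %d intervals", path, len(intervals))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """4-column bedGraph reader; output sorted, overlaps and negatives rejected."""
    path = Path(path)
    records: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates or value") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative signal value {value}")
            try:
                records.append((GenomicInterval(cols[0], start, end), value))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        track = SignalTrack(records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    logger.info("read_bedgraph: %s -> %d records", path, len(track.records))
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, value in track.records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as maximal, sorted, non-overlapping intervals (strand dropped)."""
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Maximal overlap intervals of a ∩ b under half-open semantics."""
    a_merged = merge_intervals(a)
    b_merged = merge_intervals(b)
    out: list[GenomicInterval] = []
    for iv in a_merged:
        for other in b_merged:
            if other.chrom != iv.chrom:
                continue
            lo, hi = max(iv.start, other.start), min(iv.end, other.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return merge_intervals(out)


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(table)[::-1]
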