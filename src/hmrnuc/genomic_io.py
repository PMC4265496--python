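"""Readers, writers and domain records for the formats the pipeline touches.

Every coordinate in the package is 0-based, half-open ([start, end)), the
BED convention. Methylome tables are read as 0-based by default; dialects
that report 1-based positions can be converted with ``one_based=True``.

A CpG site is always addressed by the position of the C of the CG
dinucleotide on the + strand; records reported on the - strand are mapped
to the + strand C and merged by summing read counts, because methylation
of the two symmetric cytosines is treated as one observation unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("hmrnuc")

VALID_STRANDS = {"+", "-", "."}
_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CpGRecord:
    """One CpG site with methylated / total read counts.

    ``pos`` is the 0-based position of the C of the CG on the + strand.
    """

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("CpG chrom must be non-empty")
        if self.pos < 0:
            raise ValidationError("CpG position must be >= 0")
        if self.total_count <= 0:
            raise ValidationError("CpG total_count must be positive")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValidationError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]"
            )

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence over the {A,C,G,T,N} alphabet."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("sequence name must be non-empty")
        if len(self.seq) == 0:
            raise ValidationError("sequence must be non-empty")
        extra = set(self.seq) - _ALPHABET
        if extra:
            raise ValidationError(f"sequence contains invalid characters {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadReport:
    """Bookkeeping for records silently altered or removed by a reader."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_zero_coverage: int = 0
    n_merged_minus_strand: int = 0
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Methylome TSV dialect
# chrom <TAB> pos <TAB> strand <TAB> context <TAB> level <TAB> coverage
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    """Round half away from zero; deterministic across platforms."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def read_methylome(
    path: str | Path, one_based: bool = False
) -> tuple[list[CpGRecord], ReadReport]:
    """Read a per-CpG methylation table.

    Expects >= 6 tab-separated columns (chrom, pos, strand, context, level,
    coverage). meth_count is reconstructed as round(level * coverage),
    half away from zero. Records with coverage 0 are dropped and counted.
    Records on the - strand are mapped to the + strand C (pos - 1) and
    merged by summing counts. Output is sorted by (chrom, pos).
    """
    report = ReadReport()
    # (chrom, pos) -> [meth, total]
    acc: dict[tuple[str, int], list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns, got {len(parts)}"
                )
            chrom, pos_s, strand, _context, level_s, cov_s = parts[:6]
            try:
                pos = int(pos_s)
                level = float(level_s)
                coverage = int(cov_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= level <= 1.0:
                raise ValidationError(
                    f"{path}:{lineno}: methylation level {level} outside [0, 1]"
                )
            if strand not in VALID_STRANDS:
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            report.n_read += 1
            if coverage == 0:
                report.n_dropped_zero_coverage += 1
                continue
            if one_based:
                pos -= 1
            if strand == "-":
                pos -= 1
                report.n_merged_minus_strand += 1
            if pos < 0:
                raise ValidationError(f"{path}:{lineno}: negative position after mapping")
            meth = _round_half_away(level * coverage)
            key = (chrom, pos)
            if key in acc:
                acc[key][0] += meth
                acc[key][1] += coverage
            else:
                acc[key] = [meth, coverage]
    records = [
        CpGRecord(chrom, pos, m, t)
        for (chrom, pos), (m, t) in sorted(acc.items())
    ]
    report.n_kept = len(records)
    return records, report


def write_methylome(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write CpG records in the 6-column TSV dialect (strand +, context CpG)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t+\tCpG\t{r.level:.6g}\t{r.total_count}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, fmt: str = "BED") -> list[GenomicInterval]:
    """Read BED3+ intervals, returned sorted by (chrom, start)."""
    if fmt != "BED":
        raise ValueError(f"unsupported interval format {fmt!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start = int(parts[1])
                end = int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            try:
                intervals.append(GenomicInterval(parts[0], start, end, name, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences uppercased, names cut at first whitespace."""
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id  # SeqIO.id is already the first whitespace token
        if name in seen:
            raise ValidationError(f"duplicate sequence name {name!r} in {path}")
        seen.add(name)
        seqs.append(GenomeSequence(name, str(record.seq).upper()))
    return seqs


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.chrom}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph export for per-bp tracks
# ---------------------------------------------------------------------------

def write_bedgraph(
    chrom: str,
    offset: int,
    values: Sequence[float],
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write a per-bp signal as bedGraph, merging runs of equal value."""
    import numpy as np

    vals = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                v = vals[run_start]
                if not np.isnan(v):
                    fh.write(
                        f"{chrom}\t{offset + run_start}\t{offset + i}\t{v:.{precision}g}\n"
                    )
                run_start = i


def sort_key(chrom: str, pos: int) -> tuple[str, int]:
    return (chrom, pos)
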