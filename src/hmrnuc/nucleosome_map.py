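"""MNase fragment processing: size selection, midpoint counting, smoothing.

Paired-end MNase fragments whose insert length is compatible with a
mononucleosome (100-160 bp inclusive by default) are reduced to their
midpoint — the approximate dyad position — and the per-bp midpoint counts
are convolved with a Gaussian kernel to give a continuous occupancy
signal. Tracks can be normalized to genome-wide mean 1 so that samples
with different sequencing depth are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .genomic_io import GenomicInterval, ValidationError


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned mate-pair, as a half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid fragment [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # Dyad estimate; even lengths tie-break leftward (floor).
        return (self.start + self.end - 1) // 2


@dataclass
class OccupancyTrack:
    """Per-bp nucleosome signal over [offset, offset + len(values))."""

    chrom: str
    offset: int
    values: np.ndarray
    sigma: float
    n_fragments: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("track values must be 1-D")
        if np.any(self.values < 0):
            raise ValidationError("track values must be non-negative")

    @property
    def end(self) -> int:
        return self.offset + len(self.values)

    def value_at(self, pos: int) -> float:
        """Signal at an absolute genomic position; NaN outside the track."""
        i = pos - self.offset
        if 0 <= i < len(self.values):
            return float(self.values[i])
        return float("nan")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped: int
    min_len: int
    max_len: int
    length_histogram: dict[int, int] = field(default_factory=dict)


def filter_fragments(
    fragments: Iterable[FragmentRecord],
    min_len: int = 100,
    max_len: int = 160,
) -> tuple[list[FragmentRecord], FilterReport]:
    """Keep fragments with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    kept: list[FragmentRecord] = []
    hist: dict[int, int] = {}
    n_input = 0
    for f in fragments:
        n_input += 1
        if min_len <= f.length <= max_len:
            kept.append(f)
            hist[f.length] = hist.get(f.length, 0) + 1
    report = FilterReport(
        n_input=n_input,
        n_kept=len(kept),
        n_dropped=n_input - len(kept),
        min_len=min_len,
        max_len=max_len,
        length_histogram=dict(sorted(hist.items())),
    )
    return kept, report


def midpoint_counts(
    fragments: Sequence[FragmentRecord], chrom_length: int | None = None
) -> np.ndarray:
    """Per-bp integer midpoint counts over [0, chrom_length).

    Each fragment adds 1 at floor((start + end - 1) / 2). The array length
    defaults to the largest fragment end seen.
    """
    frags = list(fragments)
    chroms = {f.chrom for f in frags}
    if len(chroms) > 1:
        raise ValidationError(f"fragments span multiple chromosomes: {sorted(chroms)}")
    if chrom_length is None:
        chrom_length = max((f.end for f in frags), default=0)
    counts = np.zeros(chrom_length, dtype=np.int64)
    if frags:
        mids = np.array([f.midpoint for f in frags], dtype=np.int64)
        if mids.max(initial=-1) >= chrom_length:
            raise ValidationError("fragment midpoint beyond chrom_length")
        np.add.at(counts, mids, 1)
    return counts


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Discrete Gaussian kernel, truncated at +/- truncate*sigma, sum 1."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return np.array([1.0])
    radius = int(np.ceil(truncate * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_track(
    counts: np.ndarray,
    sigma: float = 20.0,
    chrom: str = "chr",
    offset: int = 0,
    truncate: float = 4.0,
) -> OccupancyTrack:
    """Gaussian-smooth a midpoint count array into an occupancy track.

    Kernel mass falling outside the array is dropped (no reflection), so
    only interior impulses conserve mass exactly.
    """
    counts = np.asarray(counts, dtype=float)
    n_frag = int(round(counts.sum()))
    if sigma == 0:
        values = counts.copy()
    else:
        kernel = gaussian_kernel(sigma, truncate)
        values = fftconvolve(counts, kernel, mode="same")
        np.clip(values, 0.0, None, out=values)  # scrub FFT round-off negatives
    return OccupancyTrack(
        chrom=chrom, offset=offset, values=values, sigma=float(sigma), n_fragments=n_frag
    )


def normalize_track(track: OccupancyTrack, mode: str = "mean_one") -> OccupancyTrack:
    """Scale so the track-wide mean is 1.0."""
    if mode != "mean_one":
        raise ValueError(f"unknown normalization mode {mode!r}")
    mean = float(track.values.mean()) if len(track.values) else 0.0
    if mean <= 0:
        raise ValidationError("cannot normalize a track with zero total mass")
    return OccupancyTrack(
        chrom=track.chrom,
        offset=track.offset,
        values=track.values / mean,
        sigma=track.sigma,
        n_fragments=track.n_fragments,
    )


def build_track(
    fragments: Iterable[FragmentRecord],
    chrom_length: int | None = None,
    min_len: int = 100,
    max_len: int = 160,
    sigma: float = 20.0,
    normalize: bool = False,
) -> tuple[OccupancyTrack, FilterReport]:
    """Size-select, count midpoints and smooth, in one call."""
    kept, report = filter_fragments(fragments, min_len=min_len, max_len=max_len)
    if not kept:
        raise ValidationError("no fragments pass the insert-length filter")
    chrom = kept[0].chrom
    counts = midpoint_counts(kept, chrom_length=chrom_length)
    track = smooth_track(counts, sigma=sigma, chrom=chrom)
    if normalize:
        track = normalize_track(track)
    return track, report


# ---------------------------------------------------------------------------
# Fragment BED I/O
# ---------------------------------------------------------------------------

def read_fragments_bed(path: str | Path) -> list[FragmentRecord]:
    """Read fragments from BED3+ (one interval per mate pair)."""
    from .genomic_io import read_intervals

    return [FragmentRecord(iv.chrom, iv.start, iv.end) for iv in read_intervals(path)]


def write_fragments_bed(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def fragments_to_intervals(fragments: Iterable[FragmentRecord]) -> list[GenomicInterval]:
    return [GenomicInterval(f.chrom, f.start, f.end) for f in fragments]
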