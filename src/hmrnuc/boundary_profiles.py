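"""Anchor-aligned occupancy profiles, heatmap matrices and phasing period.

A metaprofile averages a signal track over windows centered on anchor
positions (HMR boundaries, TSSs, ...). Offsets falling outside the track
are masked — per-offset counts are kept so means near chromosome ends
stay unbiased rather than being dragged toward zero. 3'-side anchors can
be mirrored so that "into the methylated flank" points the same way for
both boundaries and the two sides pool into one profile; the unmirrored
orientation is the 5'-anchor convention (methylated flank at negative
offsets).

The phasing period of a profile is estimated as the lag of the maximum
of its mean-subtracted autocorrelation within a search window of
plausible nucleosome repeat lengths (120-260 bp by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import ValidationError
from .hmr_caller import HMRInterval
from .nucleosome_map import OccupancyTrack


@dataclass(frozen=True)
class Anchor:
    """A boundary anchor: position plus which side of the region it is."""

    chrom: str
    pos: int
    side: str = "5prime"

    def __post_init__(self) -> None:
        if self.side not in ("5prime", "3prime"):
            raise ValidationError(f"invalid anchor side {self.side!r}")


@dataclass
class MetaProfile:
    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    anchor_mode: str = ""

    @property
    def flank(self) -> int:
        return int(self.offsets[-1])


@dataclass
class HeatmapMatrix:
    """One row per interval, anchored at a boundary, sorted by length."""

    values: np.ndarray  # (n_rows, n_offsets), NaN where masked
    offsets: np.ndarray
    row_lengths: np.ndarray
    ascending: bool = True


def anchors_from_hmrs(
    hmrs: Sequence[HMRInterval],
    mode: str = "first_unmeth",
    sides: Sequence[str] = ("5prime", "3prime"),
) -> list[Anchor]:
    """Collect defined boundary anchors of the given convention."""
    out = []
    for hmr in hmrs:
        for side in sides:
            table = hmr.boundary_5 if side == "5prime" else hmr.boundary_3
            pos = table.get(mode)
            if pos is not None:
                out.append(Anchor(hmr.chrom, pos, side))
    return out


def metaprofile(
    track: OccupancyTrack,
    anchors: Sequence[Anchor],
    flank: int = 2000,
    orient: bool = True,
    anchor_mode: str = "",
) -> MetaProfile:
    """Average the track over anchor-centered windows.

    With ``orient`` on, 3'-side anchors are mirrored (the track is read
    rightward from the anchor as offset -> -offset) so both boundary
    sides share the 5' orientation. Offsets beyond the track are excluded
    from that anchor's contribution.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValidationError("metaprofile needs at least one anchor")
    width = 2 * flank + 1
    total = np.zeros(width)
    n = np.zeros(width, dtype=np.int64)
    values = track.values
    for a in anchors:
        if a.chrom != track.chrom:
            continue
        lo = a.pos - flank - track.offset
        hi = a.pos + flank + 1 - track.offset
        clo, chi = max(lo, 0), min(hi, len(values))
        if clo >= chi:
            continue
        window = values[clo:chi]
        wlo, whi = clo - lo, chi - lo  # within [0, width)
        if orient and a.side == "3prime":
            total[width - whi : width - wlo] += window[::-1]
            n[width - whi : width - wlo] += 1
        else:
            total[wlo:whi] += window
            n[wlo:whi] += 1
    if n.sum() == 0:
        raise ValidationError("no anchor overlaps the track")
    mean = np.full(width, np.nan)
    np.divide(total, n, out=mean, where=n > 0)
    return MetaProfile(
        offsets=np.arange(-flank, flank + 1), mean=mean, n=n, anchor_mode=anchor_mode
    )


def heatmap_matrix(
    track: OccupancyTrack,
    hmrs: Sequence[HMRInterval],
    anchor_side: str = "5prime",
    flank: int = 2000,
    sort_key: str = "length",
    anchor_mode: str = "first_unmeth",
    ascending: bool = True,
) -> HeatmapMatrix:
    """Per-interval occupancy rows anchored at one boundary, length-sorted."""
    if sort_key != "length":
        raise ValueError(f"unsupported sort key {sort_key!r}")
    if anchor_side not in ("5prime", "3prime"):
        raise ValueError(f"invalid anchor side {anchor_side!r}")
    width = 2 * flank + 1
    rows = []
    lengths = []
    for hmr in hmrs:
        table = hmr.boundary_5 if anchor_side == "5prime" else hmr.boundary_3
        pos = table.get(anchor_mode)
        if pos is None or hmr.chrom != track.chrom:
            continue
        row = np.full(width, np.nan)
        lo = pos - flank - track.offset
        hi = pos + flank + 1 - track.offset
        clo, chi = max(lo, 0), min(hi, len(track.values))
        if clo < chi:
            row[clo - lo : chi - lo] = track.values[clo:chi]
        rows.append(row)
        lengths.append(hmr.interval.length)
    if not rows:
        return HeatmapMatrix(
            values=np.zeros((0, width)),
            offsets=np.arange(-flank, flank + 1),
            row_lengths=np.zeros(0, dtype=int),
            ascending=ascending,
        )
    lengths_arr = np.array(lengths)
    order = np.argsort(lengths_arr, kind="stable")
    if not ascending:
        order = order[::-1]
    return HeatmapMatrix(
        values=np.vstack(rows)[order],
        offsets=np.arange(-flank, flank + 1),
        row_lengths=lengths_arr[order],
        ascending=ascending,
    )


@dataclass
class PeriodicityResult:
    period: int
    prominence: float
    autocorr: np.ndarray  # normalized autocorrelation at lags 0..max_lag
    null_threshold: float = float("nan")


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x0 = x - x.mean()
    var = float(np.dot(x0, x0)) / len(x0)
    if var <= 0:
        return np.zeros(max_lag + 1)
    ac = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        ac[lag] = np.dot(x0[: len(x0) - lag], x0[lag:]) / (len(x0) - lag) / var
    return ac


def estimate_periodicity(
    profile: MetaProfile | np.ndarray,
    search_range: tuple[int, int] = (120, 260),
    n_permutations: int = 0,
    seed: int = 0,
) -> PeriodicityResult:
    """Dominant repeat length of a profile by autocorrelation.

    Returns the lag of the autocorrelation maximum within
    ``search_range`` and its value (prominence). With
    ``n_permutations`` > 0, also the 95th percentile of the null maxima
    obtained by shuffling the profile values.
    """
    if isinstance(profile, MetaProfile):
        x = profile.mean[profile.n > 0]
    else:
        x = np.asarray(profile, dtype=float)
        x = x[~np.isnan(x)]
    lo, hi = search_range
    if lo < 1 or hi <= lo:
        raise ValidationError(f"invalid search range {search_range}")
    if len(x) <= hi + 1:
        raise ValidationError(
            f"profile of {len(x)} points is shorter than the search range (needs > {hi + 1})"
        )
    ac = _autocorr(x, hi)
    lag = int(lo + np.argmax(ac[lo : hi + 1]))
    prominence = float(ac[lag])
    null_thr = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_permutations)
        for i in range(n_permutations):
            xs = rng.permutation(x)
            maxima[i] = _autocorr(xs, hi)[lo : hi + 1].max()
        null_thr = float(np.percentile(maxima, 95))
    return PeriodicityResult(
        period=lag, prominence=prominence, autocorr=ac, null_threshold=null_thr
    )
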