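"""Cross-tissue HMR taxonomy: common vs tissue-specific regions, CGI and
TSS overlap fractions, and extended-HMR pairs.

Two HMR sets (one per cell type) are matched one-to-one by reciprocal
overlap; matched regions are "common", the rest tissue-specific. An
extended pair is a common pair sharing one boundary exactly (within a
tolerance) while the other end of one cell's region reaches further —
the shared end is boundary 1, the short cell's far end boundary 2, and
the long cell's far end boundary 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import GenomicInterval, ValidationError
from .hmr_caller import HMRInterval


def _interval(h) -> GenomicInterval:
    return h.interval if isinstance(h, HMRInterval) else h


def _bounds(h) -> tuple[int, int]:
    """(left, right) boundary anchors: first-unmethylated CpGs when
    available, otherwise the interval ends."""
    if isinstance(h, HMRInterval):
        left = h.boundary_5.get("first_unmeth", h.interval.start)
        right = h.boundary_3.get("first_unmeth", h.interval.end)
        return left, right
    return h.start, h.end


@dataclass
class HmrClassLabel:
    label: str  # common | a_specific | b_specific
    partner_index: int | None = None


@dataclass
class HmrClassification:
    labels_a: list[HmrClassLabel]
    labels_b: list[HmrClassLabel]
    pairs: list[tuple[int, int]]

    @property
    def n_common(self) -> int:
        return len(self.pairs)


def _overlapping_pairs(hmrs_a, hmrs_b) -> list[tuple[int, int, int]]:
    """(i, j, overlap_bp) for every overlapping cross-set pair (sweep)."""
    by_chrom_b: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, h in enumerate(hmrs_b):
        iv = _interval(h)
        by_chrom_b.setdefault(iv.chrom, []).append((j, iv))
    for lst in by_chrom_b.values():
        lst.sort(key=lambda t: t[1].start)
    out = []
    for i, h in enumerate(hmrs_a):
        iva = _interval(h)
        candidates = by_chrom_b.get(iva.chrom, [])
        starts = [iv.start for _, iv in candidates]
        # overlapping b intervals satisfy b.start < a.end and b.end > a.start
        hi = np.searchsorted(starts, iva.end, side="left")
        for j, ivb in candidates[:hi]:
            ov = iva.overlap_bp(ivb)
            if ov > 0:
                out.append((i, j, ov))
    return out


def classify_hmrs(
    hmrs_a: Sequence,
    hmrs_b: Sequence,
    overlap_frac: float = 0.5,
) -> HmrClassification:
    """Label HMRs common / tissue-specific by reciprocal overlap.

    A pair qualifies when the shared span covers at least
    ``overlap_frac`` of each region. Matching is one-to-one, greedy by
    largest shared span; ties break toward the leftmost partner.
    """
    if not 0 < overlap_frac <= 1:
        raise ValidationError("overlap_frac must be in (0, 1]")
    candidates = []
    for i, j, ov in _overlapping_pairs(hmrs_a, hmrs_b):
        la = _interval(hmrs_a[i]).length
        lb = _interval(hmrs_b[j]).length
        if ov >= overlap_frac * la and ov >= overlap_frac * lb:
            candidates.append((i, j, ov))
    candidates.sort(
        key=lambda t: (-t[2], _interval(hmrs_a[t[0]]).start, _interval(hmrs_b[t[1]]).start)
    )
    matched_a: dict[int, int] = {}
    matched_b: dict[int, int] = {}
    for i, j, _ in candidates:
        if i not in matched_a and j not in matched_b:
            matched_a[i] = j
            matched_b[j] = i
    labels_a = [
        HmrClassLabel("common", matched_a[i]) if i in matched_a else HmrClassLabel("a_specific")
        for i in range(len(hmrs_a))
    ]
    labels_b = [
        HmrClassLabel("common", matched_b[j]) if j in matched_b else HmrClassLabel("b_specific")
        for j in range(len(hmrs_b))
    ]
    return HmrClassification(
        labels_a=labels_a,
        labels_b=labels_b,
        pairs=sorted(matched_a.items()),
    )


@dataclass
class OverlapFractionResult:
    fraction: float
    n_overlapping: int
    n_total: int
    overlaps: np.ndarray  # per-HMR bool


def cgi_overlap_fraction(hmrs: Sequence, cgis: Sequence) -> OverlapFractionResult:
    """Fraction of HMRs sharing >= 1 bp with any CGI."""
    hmr_list = list(hmrs)
    if not hmr_list:
        raise ValidationError("cannot compute overlap fraction of an empty HMR set")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {_interval(c).chrom for c in cgis}:
        ivs = sorted(
            (_interval(c) for c in cgis if _interval(c).chrom == chrom),
            key=lambda iv: iv.start,
        )
        starts = np.array([iv.start for iv in ivs])
        # running max of ends lets a binary search answer "any end > x?"
        ends_cummax = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
        by_chrom[chrom] = (starts, ends_cummax)
    flags = np.zeros(len(hmr_list), dtype=bool)
    for idx, h in enumerate(hmr_list):
        iv = _interval(h)
        if iv.chrom not in by_chrom:
            continue
        starts, ends_cummax = by_chrom[iv.chrom]
        k = np.searchsorted(starts, iv.end, side="left")  # cgis with start < end
        flags[idx] = k > 0 and ends_cummax[k - 1] > iv.start
    n_overlap = int(flags.sum())
    return OverlapFractionResult(
        fraction=n_overlap / len(hmr_list),
        n_overlapping=n_overlap,
        n_total=len(hmr_list),
        overlaps=flags,
    )


@dataclass
class ExtendedHmrPair:
    chrom: str
    shared_boundary: int  # boundary 1
    short_boundary: int  # boundary 2
    long_boundary: int  # boundary 3
    extended_in: str  # cell label
    index_a: int
    index_b: int

    def __post_init__(self) -> None:
        if self.extension_length <= 0:
            raise ValidationError("extension length must be positive")
        lo, hi = sorted((self.shared_boundary, self.long_boundary))
        if not lo < self.short_boundary < hi:
            raise ValidationError("boundary 2 must lie strictly between boundaries 1 and 3")

    @property
    def extension_length(self) -> int:
        return abs(self.long_boundary - self.short_boundary)


def find_extended_pairs(
    hmrs_a: Sequence,
    hmrs_b: Sequence,
    identical_tol: int = 0,
    label_a: str = "a",
    label_b: str = "b",
) -> list[ExtendedHmrPair]:
    """Overlapping cross-set pairs sharing exactly one boundary.

    One side must match within ``identical_tol`` bp and the other differ
    by more; pairs identical at both ends are excluded.
    """
    pairs: list[ExtendedHmrPair] = []
    for i, j, _ in _overlapping_pairs(hmrs_a, hmrs_b):
        la, ra = _bounds(hmrs_a[i])
        lb, rb = _bounds(hmrs_b[j])
        left_same = abs(la - lb) <= identical_tol
        right_same = abs(ra - rb) <= identical_tol
        if left_same == right_same:  # both identical or both different
            continue
        if left_same:
            shared = la
            oa, ob = ra, rb
        else:
            shared = ra
            oa, ob = la, lb
        # boundary 2 = nearer far-end, boundary 3 = farther far-end
        if abs(oa - shared) < abs(ob - shared):
            b2, b3, extended_in = oa, ob, label_b
        else:
            b2, b3, extended_in = ob, oa, label_a
        lo, hi = sorted((shared, b3))
        if not lo < b2 < hi:
            continue  # far ends on opposite sides of the shared boundary
        pairs.append(
            ExtendedHmrPair(
                chrom=_interval(hmrs_a[i]).chrom,
                shared_boundary=shared,
                short_boundary=b2,
                long_boundary=b3,
                extended_in=extended_in,
                index_a=i,
                index_b=j,
            )
        )
    return pairs


def extension_summary(pairs: Sequence[ExtendedHmrPair]) -> dict[str, float]:
    if not pairs:
        return {"n": 0, "mean": float("nan"), "median": float("nan")}
    lengths = np.array([p.extension_length for p in pairs], dtype=float)
    return {"n": len(pairs), "mean": float(lengths.mean()), "median": float(np.median(lengths))}


@dataclass
class TssProximityResult:
    labels: list[str]  # contains_tss | within_2kb | distal
    fractions: dict[str, float]


def tss_proximity(
    hmrs: Sequence,
    tss_positions: Sequence[tuple[str, int]],
    within: int = 2000,
) -> TssProximityResult:
    """Classify each HMR by its nearest TSS.

    contains_tss when a TSS lies inside the interval; within_2kb when the
    nearest TSS is at most ``within`` bp away; distal otherwise.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in tss_positions}:
        by_chrom[chrom] = np.array(sorted(p for c, p in tss_positions if c == chrom))
    labels = []
    for h in hmrs:
        iv = _interval(h)
        pos = by_chrom.get(iv.chrom)
        if pos is None or len(pos) == 0:
            labels.append("distal")
            continue
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        if hi > lo:
            labels.append("contains_tss")
            continue
        dist = np.inf
        if lo > 0:
            dist = min(dist, iv.start - pos[lo - 1])
        if lo < len(pos):
            dist = min(dist, pos[lo] - (iv.end - 1))
        labels.append("within_2kb" if dist <= within else "distal")
    n = max(len(labels), 1)
    fractions = {
        key: labels.count(key) / n for key in ("contains_tss", "within_2kb", "distal")
    }
    return TssProximityResult(labels=labels, fractions=fractions)
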