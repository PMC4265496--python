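"""Sequence features at boundary CpGs: peak strata, 6-mer enrichment,
observed/expected positional motif ratios, and ROC/AUC of predictors.

Boundary nucleosome "peak scores" are window means of the occupancy
track around each boundary; the score distribution is cut at its
20th/80th percentiles into bottom/mid/top strata. The k-mer centered on
each boundary CpG (CG at window positions 3-4 for k = 6) is compared
between the top and bottom strata; 3'-side boundaries are
reverse-complemented first so the CG always reads in the same
orientation. The observed/expected analysis walks CG sites outward
(negative indices) and inward (positive) from the boundary CpG and
compares the per-index motif frequency with the genome-wide frequency
over all CG-centered windows.

AUC uses the rank (Mann-Whitney) formulation with midrank ties, which
makes it invariant under strictly monotone transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genomic_io import GenomeSequence, ValidationError
from .hmr_caller import HMRInterval
from .inos_model import revcomp
from .boundary_profiles import Anchor
from .nucleosome_map import OccupancyTrack


@dataclass
class BoundaryPeakScore:
    anchor: Anchor
    score: float
    stratum: str  # top20 | mid | bottom20


def boundary_peak_scores(
    track: OccupancyTrack,
    boundaries: Sequence[Anchor],
    halfwidth: int = 73,
) -> list[BoundaryPeakScore]:
    """Mean occupancy over [b - halfwidth, b + halfwidth] per boundary,
    stratified at the 20th/80th percentiles of the scores.

    Boundaries at the track edge get a masked mean over the defined
    positions. Percentile ties resolve by input (position) order.
    """
    boundaries = list(boundaries)
    if not boundaries:
        raise ValidationError("no boundaries given")
    scores = np.empty(len(boundaries))
    for i, b in enumerate(boundaries):
        if b.chrom != track.chrom:
            scores[i] = np.nan
            continue
        lo = max(b.pos - halfwidth - track.offset, 0)
        hi = min(b.pos + halfwidth + 1 - track.offset, len(track.values))
        scores[i] = track.values[lo:hi].mean() if hi > lo else np.nan
    defined = np.flatnonzero(~np.isnan(scores))
    if len(defined) == 0:
        raise ValidationError("no boundary overlaps the track")
    n = len(defined)
    n_cut = int(round(0.2 * n))
    # stable sort on score keeps input order among ties
    order = defined[np.argsort(scores[defined], kind="stable")]
    strata = {}
    for rank_i, idx in enumerate(order):
        if rank_i < n_cut:
            strata[idx] = "bottom20"
        elif rank_i >= n - n_cut:
            strata[idx] = "top20"
        else:
            strata[idx] = "mid"
    return [
        BoundaryPeakScore(anchor=boundaries[i], score=float(scores[i]), stratum=strata[i])
        for i in defined
    ]


@dataclass
class KmerReport:
    kmers: list[str]
    n_skipped_not_cg: int
    n_skipped_edge: int


def boundary_kmer_table(
    genome: GenomeSequence,
    boundaries: Sequence[Anchor],
    k: int = 6,
) -> KmerReport:
    """The k-mer centered on each boundary CG (CG at positions k/2-1, k/2).

    Boundaries whose genome bases are not CG, or whose window runs off
    the chromosome, are skipped and counted. 3'-side windows are
    reverse-complemented so the CG orientation is consistent.
    """
    if k % 2 != 0:
        raise ValidationError("k must be even so the CG sits centrally")
    seq = genome.seq
    left = k // 2 - 1
    kmers: list[str] = []
    n_not_cg = 0
    n_edge = 0
    for b in boundaries:
        if b.chrom != genome.chrom:
            n_edge += 1
            continue
        start = b.pos - left
        end = start + k
        if start < 0 or end > len(seq):
            n_edge += 1
            continue
        if seq[b.pos : b.pos + 2] != "CG":
            n_not_cg += 1
            continue
        window = seq[start:end]
        if "N" in window:
            n_edge += 1
            continue
        kmers.append(revcomp(window) if b.side == "3prime" else window)
    return KmerReport(kmers=kmers, n_skipped_not_cg=n_not_cg, n_skipped_edge=n_edge)


def kmer_enrichment(
    kmers_top: Sequence[str],
    kmers_bottom: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-k-mer frequencies in two strata and their log2 ratio.

    Frequencies are raw counts / set size (they sum to 1 per stratum);
    the ratio adds a one-pseudocount-equivalent epsilon per set before
    taking logs. Sorted by descending ratio.
    """
    if not kmers_top or not kmers_bottom:
        raise ValidationError("both strata must be non-empty")
    n_top, n_bot = len(kmers_top), len(kmers_bottom)
    all_kmers = sorted(set(kmers_top) | set(kmers_bottom))
    ct = pd.Series(kmers_top).value_counts()
    cb = pd.Series(kmers_bottom).value_counts()
    rows = []
    for km in all_kmers:
        t = int(ct.get(km, 0))
        b = int(cb.get(km, 0))
        ft, fb = t / n_top, b / n_bot
        ratio = np.log2((ft + pseudocount / n_top) / (fb + pseudocount / n_bot))
        rows.append((km, t, b, ft, fb, ratio))
    df = pd.DataFrame(
        rows,
        columns=["kmer", "count_top", "count_bottom", "freq_top", "freq_bottom", "log2_ratio"],
    )
    return df.sort_values("log2_ratio", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# Observed / expected positional ratios
# ---------------------------------------------------------------------------

def cg_positions(genome: GenomeSequence) -> np.ndarray:
    """Sorted positions of the C of every CG dinucleotide."""
    from .inos_model import encode

    codes = encode(genome.seq)
    return np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))


def _centered_kmer(seq: str, pos: int, k: int, rc: bool) -> str | None:
    start = pos - (k // 2 - 1)
    if start < 0 or start + k > len(seq):
        return None
    window = seq[start : start + k]
    if "N" in window:
        return None
    return revcomp(window) if rc else window


def genome_pattern_rate(genome: GenomeSequence, pattern: str = "CACGTG") -> float:
    """Fraction of all CG-centered windows genome-wide that match the pattern."""
    k = len(pattern)
    seq = genome.seq
    n_match = 0
    n_total = 0
    for pos in cg_positions(genome):
        km = _centered_kmer(seq, int(pos), k, rc=False)
        if km is None:
            continue
        n_total += 1
        if km == pattern:
            n_match += 1
    if n_total == 0:
        raise ValidationError("genome has no CG-centered windows")
    return n_match / n_total


def obs_exp_positional(
    genome: GenomeSequence,
    hmrs: Sequence[HMRInterval],
    pattern: str = "CACGTG",
    cg_offsets: Sequence[int] = tuple(range(-5, 6)),
) -> pd.DataFrame:
    """Observed/expected pattern frequency at CG sites indexed from the
    boundary CpG (index 0 = first unmethylated CG; negative = outward,
    positive = inward), pooled over both boundary sides.

    Expected is the genome-wide frequency over all CG-centered windows.
    """
    k = len(pattern)
    if k % 2 != 0 or pattern[k // 2 - 1 : k // 2 + 1] != "CG":
        raise ValidationError("pattern must have a central CG")
    expected = genome_pattern_rate(genome, pattern)
    cg_all = cg_positions(genome)
    seq = genome.seq
    obs_counts = {o: 0 for o in cg_offsets}
    obs_totals = {o: 0 for o in cg_offsets}
    for hmr in hmrs:
        if hmr.chrom != genome.chrom:
            continue
        for side in ("5prime", "3prime"):
            table = hmr.boundary_5 if side == "5prime" else hmr.boundary_3
            b = table.get("first_unmeth")
            if b is None:
                continue
            i0 = int(np.searchsorted(cg_all, b))
            if i0 >= len(cg_all) or cg_all[i0] != b:
                continue  # boundary not at a genomic CG (edited/stale)
            # inward = toward the HMR interior
            inward = 1 if side == "5prime" else -1
            for o in cg_offsets:
                i = i0 + o * inward
                if not 0 <= i < len(cg_all):
                    continue
                km = _centered_kmer(seq, int(cg_all[i]), k, rc=(side == "3prime"))
                if km is None:
                    continue
                obs_totals[o] += 1
                if km == pattern:
                    obs_counts[o] += 1
    rows = []
    for o in cg_offsets:
        tot = obs_totals[o]
        obs = obs_counts[o] / tot if tot else float("nan")
        rows.append((o, obs_counts[o], tot, obs, expected, obs / expected if tot else float("nan")))
    return pd.DataFrame(
        rows, columns=["cg_index", "n_match", "n_sites", "observed", "expected", "ratio"]
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """AUC by the midrank Mann-Whitney statistic, plus the ROC polygon."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(s) != len(y):
        raise ValidationError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thresholds)


def cg_indicator(genome: GenomeSequence, positions: Sequence[int]) -> np.ndarray:
    """Binary predictor: is there a CG dinucleotide at each position."""
    seq = genome.seq
    out = np.zeros(len(positions))
    for i, p in enumerate(positions):
        out[i] = 1.0 if 0 <= p < len(seq) - 1 and seq[p : p + 2] == "CG" else 0.0
    return out
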