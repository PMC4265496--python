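"""Synthetic genomes, methylomes and MNase fragments with full ground truth.

The generator emulates the statistical structure the boundary analysis
assumes, so every pipeline stage can be exercised end to end and scored
against planted truth:

* an i.i.d. background genome at a configurable GC fraction with
  GC/CpG-enriched islands (CGIs) planted at non-overlapping positions;
* per-cell-type methylomes: common, tissue-specific and extended HMRs
  planted on the genome, every CpG drawn from a beta-binomial around the
  state level (hypomethylated ~0.05, methylated ~0.85) at Poisson
  coverage. CpG-free "gap zones" are carved just outside each HMR end
  and a methylated CpG is forced at a drawn distance (uniform 100-200 bp
  by default), so the first-unmethylated to adjacent-methylated CpG
  distance is a planted, recoverable quantity;
* fragment midpoints from a mixture of uniform background and phased
  nucleosome positions at boundary + k * period into the methylated
  flank, with geometrically decaying amplitudes, optionally modulated by
  local GC content (sequence-driven occupancy) and by planted motifs;
* E-box (CACGTG) planting centered on boundary CpGs at a configurable
  fraction, plus a genome-wide background rate at ordinary CpG sites.

Everything is driven by numpy Generator seeds; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genomic_io import CpGRecord, GenomeSequence, GenomicInterval, ValidationError
from .nucleosome_map import FragmentRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantedHmr:
    cell: str
    interval: GenomicInterval
    label: str  # common | a_specific | b_specific | extended_short | extended_long
    cpg_positions: tuple[int, ...] = ()
    pair_id: int | None = None

    @property
    def boundary_5(self) -> int:
        return self.cpg_positions[0]

    @property
    def boundary_3(self) -> int:
        return self.cpg_positions[-1]


@dataclass
class SimulationTruth:
    genome_length: int = 0
    cgi_intervals: list[GenomicInterval] = field(default_factory=list)
    hmrs: dict[str, list[PlantedHmr]] = field(default_factory=dict)
    extended_pairs: list[dict] = field(default_factory=list)
    planted_gaps: list[int] = field(default_factory=list)
    motif_boundary_positions: list[int] = field(default_factory=list)
    motif_background_positions: list[int] = field(default_factory=list)
    phasing_period: int | None = None
    seeds: dict[str, int] = field(default_factory=dict)

    def boundaries(self, cell: str) -> list[tuple[int, str]]:
        """(position, side) of every first-unmethylated-CpG anchor."""
        out = []
        for h in self.hmrs.get(cell, []):
            if h.cpg_positions:
                out.append((h.boundary_5, "5prime"))
                out.append((h.boundary_3, "3prime"))
        return out


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def simulate_genome(
    length: int = 5_000_000,
    gc: float = 0.42,
    cgi_spec: dict | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[GenomeSequence, SimulationTruth]:
    """I.i.d. genome at background GC with non-overlapping CGIs planted.

    ``cgi_spec`` keys: count (default 150), length (1000), gc (0.65).
    """
    spec = {"count": 150, "length": 1000, "gc": 0.65}
    spec.update(cgi_spec or {})
    count, clen, cgc = spec["count"], spec["length"], spec["gc"]
    if length < 10 * clen * count:
        raise ValidationError(
            f"genome of {length} bp cannot host {count} CGIs of {clen} bp "
            "(needs >= 10 * count * length)"
        )
    rng = np.random.default_rng(seed)
    codes = _draw_bases(rng, length, gc)
    # non-overlapping starts via the sorted-uniform construction
    free = length - count * clen
    offsets = np.sort(rng.integers(0, free, size=count))
    starts = offsets + np.arange(count) * clen
    cgis = []
    for s in starts:
        codes[s : s + clen] = _draw_bases(rng, clen, cgc)
        cgis.append(GenomicInterval(chrom, int(s), int(s + clen), name="CGI"))
    genome = GenomeSequence(chrom, _BASES[codes].tobytes().decode("ascii"))
    truth = SimulationTruth(
        genome_length=length, cgi_intervals=cgis, seeds={"genome": seed}
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

@dataclass
class HmrPlan:
    """How many HMRs of each cross-tissue class to plant, and their sizes."""

    n_common: int = 300
    n_specific_a: int = 100
    n_specific_b: int = 100
    n_extended: int = 100
    length_range: tuple[int, int] = (500, 2500)
    extension_range: tuple[int, int] = (100, 460)
    cgi_fraction_common: float = 0.363
    min_separation: int = 600


@dataclass
class MethylomeSim:
    genome: GenomeSequence
    records: dict[str, list[CpGRecord]]
    truth: SimulationTruth


def _find_cpgs(codes: np.ndarray) -> np.ndarray:
    return np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))


def _clear_cpgs_in(codes: np.ndarray, lo: int, hi: int) -> None:
    """Remove every CpG whose C lies in [lo, hi) by writing T over the C."""
    lo = max(lo, 0)
    hi = min(hi, len(codes) - 1)
    if hi <= lo:
        return
    seg_c = codes[lo:hi] == 1
    seg_g = codes[lo + 1 : hi + 1] == 2
    codes[lo:hi][seg_c & seg_g] = 3


def _force_cg(codes: np.ndarray, pos: int) -> None:
    codes[pos] = 1
    codes[pos + 1] = 2


def simulate_methylome(
    genome: GenomeSequence,
    truth: SimulationTruth,
    plan: HmrPlan | None = None,
    coverage_mean: float = 20.0,
    hypo_level: float = 0.05,
    meth_level: float = 0.85,
    dispersion: float = 0.1,
    boundary_gap: tuple[int, int] = (100, 200),
    min_cpgs: int = 4,
    seed: int = 0,
    cells: tuple[str, str] = ("a", "b"),
) -> MethylomeSim:
    """Plant HMRs on the genome and draw per-cell CpG counts.

    The genome is edited so HMR anchors are controllable: a CpG is forced
    at each planted boundary, CpGs within the drawn boundary gap are
    removed and a methylated CpG is forced exactly at the drawn distance.
    Returns the edited genome together with per-cell records and the
    completed truth.
    """
    plan = plan or HmrPlan()
    rng = np.random.default_rng(seed)
    from .inos_model import encode

    codes = encode(genome.seq).copy()
    L = len(codes)
    cell_a, cell_b = cells

    lo_len, hi_len = plan.length_range
    lo_ext, hi_ext = plan.extension_range

    # ---- plan loci -------------------------------------------------------
    loci: list[dict] = []
    n_cgi_common = int(round(plan.cgi_fraction_common * plan.n_common))
    if n_cgi_common > len(truth.cgi_intervals):
        raise ValidationError("not enough CGIs to host the planned common HMRs")
    cgi_choice = rng.choice(len(truth.cgi_intervals), size=n_cgi_common, replace=False)
    occupied: list[tuple[int, int]] = []

    def conflicts(s: int, e: int) -> bool:
        for os_, oe in occupied:
            if s < oe and os_ < e:
                return True
        return False

    sep = plan.min_separation
    for ci in cgi_choice:
        cgi = truth.cgi_intervals[int(ci)]
        length = int(rng.integers(lo_len, hi_len + 1))
        center = (cgi.start + cgi.end) // 2
        s = max(center - length // 2, sep)
        e = s + length
        if e > L - sep or conflicts(s - sep, e + sep):
            continue
        occupied.append((s - sep, e + sep))
        loci.append({"type": "common", "span": (s, e), "on_cgi": True})

    # avoid CGIs for every other locus so CGI-overlap labels stay clean
    cgi_sorted = sorted((c.start, c.end) for c in truth.cgi_intervals)

    def hits_cgi(s: int, e: int) -> bool:
        for cs, ce in cgi_sorted:
            if s < ce + sep and cs - sep < e:
                return True
        return False

    todo = (
        [("common", None)] * (plan.n_common - len(loci))
        + [("specific", cell_a)] * plan.n_specific_a
        + [("specific", cell_b)] * plan.n_specific_b
        + [("extended", None)] * plan.n_extended
    )
    max_tries = 200 * max(len(todo), 1)
    tries = 0
    for kind, cell in todo:
        length = int(rng.integers(lo_len, hi_len + 1))
        ext = int(rng.integers(lo_ext, hi_ext + 1)) if kind == "extended" else 0
        span = length + ext
        while True:
            tries += 1
            if tries > max_tries:
                raise ValidationError("could not place the planned HMRs; genome too small")
            s = int(rng.integers(sep, L - span - sep))
            e = s + span
            if not conflicts(s - sep, e + sep) and not hits_cgi(s, e):
                break
        occupied.append((s - sep, e + sep))
        locus = {"type": kind, "span": (s, e), "on_cgi": False, "cell": cell}
        if kind == "extended":
            locus["extension"] = ext
            locus["shared_side"] = "5prime" if rng.random() < 0.5 else "3prime"
            locus["extended_in"] = cell_a if rng.random() < 0.5 else cell_b
        loci.append(locus)

    # ---- edit genome and assemble intervals ------------------------------
    hmrs: dict[str, list[PlantedHmr]] = {cell_a: [], cell_b: []}
    extended_pairs: list[dict] = []
    planted_gaps: list[int] = []
    pair_id = 0

    def carve_gap(anchor: int, side: str) -> None:
        g = int(rng.integers(boundary_gap[0], boundary_gap[1] + 1))
        if side == "5prime":
            if anchor - g - 1 < 0:
                return
            _clear_cpgs_in(codes, anchor - g, anchor)
            _force_cg(codes, anchor - g)
        else:
            if anchor + g + 2 > L:
                return
            _clear_cpgs_in(codes, anchor + 1, anchor + g)
            _force_cg(codes, anchor + g)
        planted_gaps.append(g)

    def ensure_interior_cpgs(s: int, e: int) -> None:
        interior = _find_cpgs(codes[s:e])
        need = (min_cpgs + 2) - len(interior)
        guard = 0
        while need > 0 and guard < 100:
            guard += 1
            x = int(rng.integers(s + 2, e - 3))
            if codes[x] != 1 and codes[x - 1] != 1 and codes[x + 1] != 1:
                _force_cg(codes, x)
                need -= 1

    for locus in loci:
        s, e = locus["span"]
        if locus["type"] == "extended":
            ext = locus["extension"]
            if locus["shared_side"] == "5prime":
                short_iv, long_iv = (s, e - ext), (s, e)
                b1, b2, b3 = s, e - ext - 2, e - 2
                _force_cg(codes, b1)
                _force_cg(codes, b2)
                _force_cg(codes, b3)
                carve_gap(b1, "5prime")
                carve_gap(b3, "3prime")
            else:
                short_iv, long_iv = (s + ext, e), (s, e)
                b1, b2, b3 = e - 2, s + ext, s
                _force_cg(codes, b1)
                _force_cg(codes, b2)
                _force_cg(codes, b3)
                carve_gap(b1, "3prime")
                carve_gap(b3, "5prime")
            ensure_interior_cpgs(s, e)
            long_cell = locus["extended_in"]
            short_cell = cell_b if long_cell == cell_a else cell_a
            hmrs[short_cell].append(
                PlantedHmr(
                    cell=short_cell,
                    interval=GenomicInterval(genome.chrom, *short_iv),
                    label="extended_short",
                    pair_id=pair_id,
                )
            )
            hmrs[long_cell].append(
                PlantedHmr(
                    cell=long_cell,
                    interval=GenomicInterval(genome.chrom, *long_iv),
                    label="extended_long",
                    pair_id=pair_id,
                )
            )
            extended_pairs.append(
                {
                    "pair_id": pair_id,
                    "shared_side": locus["shared_side"],
                    "boundary_1": b1,
                    "boundary_2": b2,
                    "boundary_3": b3,
                    "extended_in": long_cell,
                    "extension": locus["extension"],
                }
            )
            pair_id += 1
        else:
            _force_cg(codes, s)
            _force_cg(codes, e - 2)
            carve_gap(s, "5prime")
            carve_gap(e - 2, "3prime")
            ensure_interior_cpgs(s, e)
            iv = GenomicInterval(genome.chrom, s, e)
            if locus["type"] == "common":
                hmrs[cell_a].append(PlantedHmr(cell_a, iv, "common", pair_id=pair_id))
                hmrs[cell_b].append(PlantedHmr(cell_b, iv, "common", pair_id=pair_id))
                pair_id += 1
            else:
                cell = locus["cell"]
                hmrs[cell].append(PlantedHmr(cell, iv, f"{cell}_specific"))

    genome_out = GenomeSequence(genome.chrom, _BASES[codes].tobytes().decode("ascii"))

    # ---- fill in CpG sets and draw counts --------------------------------
    cpg_pos = _find_cpgs(codes)
    for cell in (cell_a, cell_b):
        for h in hmrs[cell]:
            lo = np.searchsorted(cpg_pos, h.interval.start)
            hi = np.searchsorted(cpg_pos, h.interval.end)
            h.cpg_positions = tuple(int(p) for p in cpg_pos[lo:hi])
            if len(h.cpg_positions) < min_cpgs:
                raise ValidationError("planted HMR ended up with too few CpGs")

    conc = (1 - dispersion) / dispersion
    records: dict[str, list[CpGRecord]] = {}
    for cell in (cell_a, cell_b):
        hypo_mask = np.zeros(len(cpg_pos), dtype=bool)
        for h in hmrs[cell]:
            lo = np.searchsorted(cpg_pos, h.interval.start)
            hi = np.searchsorted(cpg_pos, h.interval.end)
            hypo_mask[lo:hi] = True
        means = np.where(hypo_mask, hypo_level, meth_level)
        levels = rng.beta(means * conc, (1 - means) * conc)
        coverage = rng.poisson(coverage_mean, size=len(cpg_pos))
        meth = rng.binomial(np.maximum(coverage, 1), levels)
        keep = coverage > 0
        records[cell] = [
            CpGRecord(genome.chrom, int(p), int(m), int(t))
            for p, m, t in zip(cpg_pos[keep], meth[keep], coverage[keep])
        ]

    truth.genome_length = L
    truth.hmrs = hmrs
    truth.extended_pairs = extended_pairs
    truth.planted_gaps = planted_gaps
    truth.seeds["methylome"] = seed
    return MethylomeSim(genome=genome_out, records=records, truth=truth)


def simulate_hmm_counts(
    n_cpgs: int = 10_000,
    hypo_level: float = 0.05,
    meth_level: float = 0.85,
    mean_block: float = 20.0,
    p_hypo: float = 0.3,
    coverage_mean: float = 10.0,
    dispersion: float = 0.1,
    spacing: int = 50,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[CpGRecord], np.ndarray]:
    """Draw CpG counts directly from a two-state chain with geometric
    block lengths (mean ``mean_block`` CpGs); returns records + true states."""
    rng = np.random.default_rng(seed)
    p_leave = 1.0 / mean_block
    states = np.empty(n_cpgs, dtype=np.int64)
    states[0] = 0 if rng.random() < p_hypo else 1
    for i in range(1, n_cpgs):
        if rng.random() < p_leave:
            states[i] = 1 - states[i - 1]
        else:
            states[i] = states[i - 1]
    means = np.where(states == 0, hypo_level, meth_level)
    conc = (1 - dispersion) / dispersion
    levels = rng.beta(means * conc, (1 - means) * conc)
    coverage = np.maximum(rng.poisson(coverage_mean, size=n_cpgs), 1)
    meth = rng.binomial(coverage, levels)
    pos = np.arange(n_cpgs) * spacing
    records = [
        CpGRecord(chrom, int(p), int(m), int(t)) for p, m, t in zip(pos, meth, coverage)
    ]
    return records, states


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def simulate_fragments(
    genome: GenomeSequence,
    truth: SimulationTruth,
    cell: str = "a",
    boundary_occupancy: float = 3.0,
    period: int = 165,
    n_phased: int = 3,
    decay: float = 0.7,
    jitter_sd: float = 20.0,
    insert_mean: float = 147.0,
    insert_sd: float = 10.0,
    insert_clip: tuple[int, int] | None = None,
    n_fragments: int = 500_000,
    gc_coupling: float = 0.0,
    sequence_bias: float = 0.0,
    motif_boost: float = 1.0,
    seed: int = 0,
) -> list[FragmentRecord]:
    """Draw paired-end fragments from background + phased boundary arrays.

    Midpoints mix a genome-wide background with Gaussian-jittered
    nucleosome positions at boundary + k * period (k = 0..n_phased-1)
    into the methylated flank, amplitudes decaying by ``decay`` per
    step. ``boundary_occupancy`` is the local peak enrichment over
    background of the k = 0 nucleosome. Two knobs make occupancy
    sequence-driven: ``gc_coupling`` scales each boundary's amplitude
    with the standardized GC fraction of its 147-bp window, and
    ``sequence_bias`` tilts the background from uniform toward
    exp(bias * z(window GC)) at every position, emulating intrinsic
    GC-preferring nucleosome affinity genome-wide. ``motif_boost``
    multiplies the amplitude at boundaries carrying a planted motif.
    Insert lengths are normal, rounded, truncated at [50, 300] (tighter
    with ``insert_clip``).
    """
    if n_fragments <= 0:
        raise ValidationError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    boundaries = truth.boundaries(cell)
    if not boundaries:
        raise ValidationError("truth carries no boundaries for this cell")

    from .inos_model import encode

    codes = encode(genome.seq)
    gc_ind = (codes == 1) | (codes == 2)

    motif_set = set(truth.motif_boundary_positions)
    centers: list[float] = []
    weights: list[float] = []
    base_amp = (boundary_occupancy - 1.0) * jitter_sd * np.sqrt(2 * np.pi) / L
    gcs = []
    for pos, side in boundaries:
        lo, hi = max(pos - 73, 0), min(pos + 74, L)
        gcs.append(gc_ind[lo:hi].mean())
    gcs_arr = np.array(gcs)
    gc_sd = gcs_arr.std()
    gc_z = (gcs_arr - gcs_arr.mean()) / gc_sd if gc_sd > 0 else np.zeros(len(gcs_arr))
    # cap the modulation so no single boundary dominates the averages
    gc_z = np.clip(gc_z, -2.0, 2.0)
    for (pos, side), z in zip(boundaries, gc_z):
        amp = base_amp * float(np.exp(gc_coupling * z))
        if pos in motif_set:
            amp *= motif_boost
        direction = -1 if side == "5prime" else 1  # into the methylated flank
        for kk in range(n_phased):
            centers.append(pos + direction * kk * period)
            weights.append(amp * decay**kk)

    comp_w = np.array([1.0] + weights)
    comp_w /= comp_w.sum()
    comp = rng.choice(len(comp_w), size=n_fragments, p=comp_w)
    mids = np.empty(n_fragments, dtype=np.int64)
    bg = comp == 0
    if sequence_bias > 0:
        from .inos_model import _sliding_sum

        win_gc = _sliding_sum(gc_ind.astype(float), 147) / 147.0
        z = (win_gc - win_gc.mean()) / max(win_gc.std(), 1e-12)
        p_bg = np.exp(sequence_bias * z)
        p_bg /= p_bg.sum()
        mids[bg] = 73 + rng.choice(len(p_bg), size=int(bg.sum()), p=p_bg)
    else:
        mids[bg] = rng.integers(0, L, size=int(bg.sum()))
    nuc = ~bg
    centers_arr = np.array(centers)
    mids[nuc] = np.round(
        centers_arr[comp[nuc] - 1] + rng.normal(0, jitter_sd, size=int(nuc.sum()))
    ).astype(np.int64)

    lengths = np.round(rng.normal(insert_mean, insert_sd, size=n_fragments)).astype(np.int64)
    np.clip(lengths, 50, 300, out=lengths)
    starts = mids - (lengths - 1) // 2
    ends = starts + lengths
    ok = (starts >= 0) & (ends <= L)
    if insert_clip is not None:
        ok &= (lengths >= insert_clip[0]) & (lengths <= insert_clip[1])
    truth.phasing_period = period
    truth.seeds["fragments"] = seed
    return [
        FragmentRecord(genome.chrom, int(s), int(e))
        for s, e in zip(starts[ok], ends[ok])
    ]


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(
    genome: GenomeSequence,
    truth: SimulationTruth,
    pattern: str = "CACGTG",
    boundary_fraction: float = 0.2,
    background_rate: float = 0.1,
    cell: str = "a",
    seed: int = 0,
) -> tuple[GenomeSequence, SimulationTruth, dict]:
    """Write the pattern centered on a random subset of boundary CpGs and
    at background CpG sites genome-wide.

    ``boundary_fraction`` is the total motif rate at boundary CpGs;
    boundaries are planted at max(boundary_fraction, background_rate),
    so with no preferential planting (fraction 0) boundaries carry the
    motif at exactly the background rate and the observed/expected
    ratio is ~1. Placements overlapping an earlier planting are skipped
    and reported; background planting avoids boundary neighborhoods
    (they are handled by the boundary pass).
    """
    k = len(pattern)
    if k % 2 != 0 or pattern[k // 2 - 1 : k // 2 + 1] != "CG":
        raise ValidationError("pattern must be even-length with a central CG")
    from .inos_model import encode
    from .motif_enrichment import cg_positions

    rng = np.random.default_rng(seed)
    codes = encode(genome.seq).copy()
    pat_codes = encode(pattern)
    left = k // 2 - 1
    L = len(codes)

    boundary_pos = sorted({pos for pos, _ in truth.boundaries(cell)})
    protected = set()
    for b in boundary_pos:
        protected.update(range(b - k, b + k + 1))

    planted: list[int] = []
    n_skipped = 0

    def try_plant(pos: int) -> bool:
        nonlocal n_skipped
        start = pos - left
        if start < 0 or start + k > L:
            n_skipped += 1
            return False
        for q in planted[-8:]:  # plantings are processed in position order
            if abs(q - pos) < k:
                n_skipped += 1
                return False
        codes[start : start + k] = pat_codes
        planted.append(pos)
        return True

    n_pick = int(round(max(boundary_fraction, background_rate) * len(boundary_pos)))
    picked = rng.choice(len(boundary_pos), size=n_pick, replace=False) if n_pick else []
    picked_set = {boundary_pos[int(i)] for i in picked}
    for pos in sorted(picked_set):
        if try_plant(pos):
            truth.motif_boundary_positions.append(pos)

    all_cg = cg_positions(genome)
    bg_candidates = [int(p) for p in all_cg if int(p) not in protected]
    n_bg = int(round(background_rate * len(bg_candidates)))
    if n_bg:
        chosen = rng.choice(len(bg_candidates), size=n_bg, replace=False)
        for pos in sorted(bg_candidates[int(i)] for i in chosen):
            if try_plant(pos):
                truth.motif_background_positions.append(pos)

    genome_out = GenomeSequence(genome.chrom, _BASES[codes].tobytes().decode("ascii"))
    truth.seeds["motifs"] = seed
    report = {"n_planted": len(planted), "n_skipped": n_skipped}
    return genome_out, truth, report


def reconcile_methylome(
    records: Sequence[CpGRecord], genome: GenomeSequence
) -> list[CpGRecord]:
    """Drop records whose position no longer carries a CG (after edits)."""
    seq = genome.seq
    return [r for r in records if seq[r.pos : r.pos + 2] == "CG"]


def refresh_truth_cpgs(truth: SimulationTruth, genome: GenomeSequence) -> None:
    """Recompute every planted HMR's CpG set from the (edited) genome."""
    from .inos_model import encode

    cpg_pos = _find_cpgs(encode(genome.seq))
    for cell_hmrs in truth.hmrs.values():
        for h in cell_hmrs:
            lo = np.searchsorted(cpg_pos, h.interval.start)
            hi = np.searchsorted(cpg_pos, h.interval.end)
            h.cpg_positions = tuple(int(p) for p in cpg_pos[lo:hi])


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    genome: GenomeSequence
    truth: SimulationTruth
    methylomes: dict[str, list[CpGRecord]]
    fragments: dict[str, list[FragmentRecord]]
    params: dict


def simulate_dataset(
    seed: int = 0,
    length: int = 5_000_000,
    plan: HmrPlan | None = None,
    cgi_spec: dict | None = None,
    n_fragments: int = 500_000,
    boundary_occupancy: float = 3.0,
    period: int = 165,
    gc_coupling: float = 0.0,
    sequence_bias: float = 0.0,
    motif_boost: float = 1.0,
    motif_boundary_fraction: float = 0.2,
    motif_background_rate: float = 0.1,
    fragment_cells: tuple[str, ...] = ("a",),
) -> SyntheticDataset:
    """Generate genome, two-cell methylomes, motifs and fragments in one go.

    Sub-seeds are derived from ``seed`` so the whole dataset is
    reproducible from a single integer.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    genome, truth = simulate_genome(length=length, cgi_spec=cgi_spec, seed=sub[0])
    sim = simulate_methylome(genome, truth, plan=plan, seed=sub[1])
    genome2, truth, motif_report = plant_motifs(
        sim.genome,
        sim.truth,
        boundary_fraction=motif_boundary_fraction,
        background_rate=motif_background_rate,
        seed=sub[2],
    )
    methylomes = {
        cell: reconcile_methylome(recs, genome2) for cell, recs in sim.records.items()
    }
    refresh_truth_cpgs(truth, genome2)
    fragments = {}
    for i, cell in enumerate(fragment_cells):
        fragments[cell] = simulate_fragments(
            genome2,
            truth,
            cell=cell,
            boundary_occupancy=boundary_occupancy,
            period=period,
            n_fragments=n_fragments,
            gc_coupling=gc_coupling,
            sequence_bias=sequence_bias,
            motif_boost=motif_boost,
            seed=sub[3] + i,
        )
    return SyntheticDataset(
        genome=genome2,
        truth=truth,
        methylomes=methylomes,
        fragments=fragments,
        params={
            "seed": seed,
            "length": length,
            "n_fragments": n_fragments,
            "boundary_occupancy": boundary_occupancy,
            "period": period,
            "gc_coupling": gc_coupling,
            "sequence_bias": sequence_bias,
            "motif_boost": motif_boost,
            "motif_boundary_fraction": motif_boundary_fraction,
            "motif_background_rate": motif_background_rate,
            "motif_report": motif_report,
        },
    )


def _scaled_plan(s: float) -> tuple[HmrPlan, dict]:
    plan = HmrPlan(
        n_common=max(int(300 * s), 10),
        n_specific_a=max(int(100 * s), 4),
        n_specific_b=max(int(100 * s), 4),
        n_extended=max(int(100 * s), 4),
    )
    return plan, {"count": max(int(150 * s), 5)}


def paperlike_dataset(seed: int = 1, scale: float = 1.0) -> SyntheticDataset:
    """The default study conditions in one call.

    A 5 Mb genome with 150 CGIs; 300 common (36.3% on CGIs), 2 x 100
    tissue-specific and 100 extended HMRs; 500k fragments with uniform
    phased boundary arrays (3-fold peak enrichment, 165-bp period, 3
    nucleosomes decaying 0.7 per step); E-box planted at 20% of
    boundaries and 10% of background CpG sites (sequence edits only —
    occupancy amplitudes are homogeneous here). ``scale`` shrinks
    genome, HMR counts and fragment depth proportionally for quick runs.
    """
    s = max(scale, 0.05)
    plan, cgi_spec = _scaled_plan(s)
    return simulate_dataset(
        seed=seed,
        length=int(5_000_000 * s),
        plan=plan,
        cgi_spec=cgi_spec,
        n_fragments=int(500_000 * s),
        boundary_occupancy=3.0,
        period=165,
        motif_boundary_fraction=0.2,
        motif_background_rate=0.1,
    )


def sequence_driven_dataset(seed: int = 1, scale: float = 1.0) -> SyntheticDataset:
    """Study conditions with sequence-driven occupancy.

    As :func:`paperlike_dataset`, but nucleosome placement depends on
    the DNA: the background tilts toward GC-rich 147-bp windows
    (sequence_bias = 1.5), each boundary array's amplitude scales with
    its window GC (gc_coupling = 1.2), and boundaries carrying a
    planted E-box bind nucleosomes 6-fold more strongly. This is the
    regime where a sequence model (INOS) can predict which boundaries
    hold nucleosomes while a bare CG indicator cannot.
    """
    s = max(scale, 0.05)
    plan, cgi_spec = _scaled_plan(s)
    return simulate_dataset(
        seed=seed,
        length=int(5_000_000 * s),
        plan=plan,
        cgi_spec=cgi_spec,
        n_fragments=int(500_000 * s),
        boundary_occupancy=3.0,
        period=165,
        gc_coupling=1.2,
        sequence_bias=1.5,
        motif_boost=6.0,
        motif_boundary_fraction=0.2,
        motif_background_rate=0.1,
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def recovery_jaccard(called_hmrs, planted: Sequence[PlantedHmr]) -> np.ndarray:
    """Best CpG-set Jaccard of each planted HMR against the called set."""
    called_sets = [set(h.cpg_positions) for h in called_hmrs]
    out = np.zeros(len(planted))
    for i, p in enumerate(planted):
        pset = set(p.cpg_positions)
        best = 0.0
        for cs in called_sets:
            inter = len(pset & cs)
            if inter == 0:
                continue
            j = inter / len(pset | cs)
            best = max(best, j)
        out[i] = best
    return out
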