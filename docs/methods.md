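# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `hmrnuc`, in the spirit of the methods sections
that simulation and statistics packages ship alongside their APIs. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and input dialects

All coordinates are 0-based and half-open, the BED convention; BED
files are read and written verbatim. Methylome tables are 6-column TSV
(chrom, pos, strand, context, level, coverage). Positions are taken as
0-based; 1-based dialects convert with `one_based=True` (CLI
`--one-based-meth`). A CpG is always addressed by the C of the CG on
the + strand; − strand records map to `pos − 1` and merge by summing
counts, because the two symmetric cytosines are one biological
observation. Methylated counts are reconstructed as
`round(level × coverage)`, rounding half away from zero so the result
does not depend on the platform's banker's rounding. Zero-coverage
records are dropped and counted in the read report.

## Occupancy tracks

Mononucleosome-sized inserts are selected with inclusive bounds
(default 100–160 bp). Fragment midpoints use `floor((start+end−1)/2)`,
i.e. even lengths tie-break leftward — a documented, deterministic
choice. Smoothing uses a discrete Gaussian kernel truncated at ±4σ and
renormalized to unit mass; σ defaults to 20 bp, wide enough to suppress
bp-level counting noise while leaving a 165-bp repeat clearly resolved
(a kernel much above ~40 bp would begin to blur it). Kernel mass
falling off the array is dropped rather than reflected: means near
edges are then slightly deficient, which is why all anchored averaging
downstream masks undefined offsets instead of zero-filling.
Convolution is performed by FFT; round-off can produce values at
~−1e-15, which are clipped to zero to preserve the non-negativity
invariant. `normalize_track` rescales to genome-wide mean 1 so samples
of different depth are comparable.

## The HMR caller

States: HYPO and METH over the sequence of CpGs (transitions are
per-CpG-step, independent of genomic distance — a known simplification;
CpG deserts are handled separately, see below). Emissions are
beta-binomial: for state *s*, `m | n ~ BetaBin(n, α_s, β_s)`, which
absorbs the overdispersion of bisulfite counts that a plain binomial
underestimates.

Fitting is Baum–Welch with a scaled forward–backward pass (compiled
with numba; the 2-state recursion over hundreds of thousands of CpGs is
the pipeline's only sequential hot loop). The emission M-step uses
weighted moment matching: with posterior weights, the mean level μ and
level variance v give the intra-class correlation
`ρ = (v/(μ(1−μ)) − E[1/n]) / (1 − E[1/n])` (the `E[1/n]` term removes
the binomial sampling component), hence concentration `(1−ρ)/ρ` and
(α, β) = (μ, 1−μ)·concentration, clamped to [1e−3, 1e4] with
ρ ∈ [1e−4, 0.9]. Moment matching alone does not guarantee likelihood
ascent, so each emission update is accepted only if it increases its
expected complete-data term; transition and initial-state updates are
exact M-steps. The overall iteration is therefore a generalized EM and
the log-likelihood is non-decreasing, which the tests assert on every
iteration of 50 random datasets. Initialization uses levels ≈0.08/0.80
with mild seeded jitter; convergence is |Δ log L| < 1e−4 (default),
with a warning flag when the iteration cap is reached. After fitting,
states are relabeled so HYPO has the lower expected level.

Decoding is posterior-based (P(hypo) > 0.5) rather than Viterbi — at
the coverage this data has, per-site posteriors are near 0/1 and the
two decoders agree; posterior decoding keeps the per-site confidence
available. Runs shorter than `min_cpgs = 4` are discarded; runs
spanning an inter-CpG gap > 10 kb are split so unsequenced deserts do
not bridge distinct regions. The called interval spans the first to
last HYPO CpG + 1.

Boundary conventions per side: `first_unmeth` (outermost HMR CpG),
`second_unmeth` (next inward; undefined for single-CpG regions),
`adjacent_meth` (nearest CpG outside; undefined at chromosome ends).
Boundary-gap statistics summarize the first-unmeth → adjacent-meth
distance over both sides.

## INOS

Features of a 147-bp window: counts of all reverse-complement-collapsed
k-mers, k = 1..4 (2 + 10 + 32 + 136 = 180 classes), each normalized by
the number of window positions for that k (147 − k + 1), plus GC
fraction — 181 features. Collapsing makes featurization of a sequence
and of its reverse complement identical by construction. Note that the
collapsed 1-mer C/G class equals the GC fraction; the Lasso's
variable selection handles the redundancy.

The Lasso is fitted by cyclic coordinate descent with soft
thresholding on z-scored features, minimizing `(1/2n)‖y − Xw − b‖² +
λ‖w‖₁`; the objective is checked to be non-increasing after every
sweep, and the z-scoring is folded back into the stored weights so the
model applies to raw features. At λ = 0 it reproduces least squares; at
λ ≥ max|X̃ᵀỹ|/n all weights are exactly zero. λ defaults to 5e−4 in the
training helpers — small, because the feature set (181) is modest
relative to the training samples (thousands) and the goal is mild
selection, not aggressive sparsification.

Genome scoring exploits linearity: for each k the per-position k-mer
weight array is slid with a windowed sum (computed in ~1 Mb chunks so
cumulative-sum round-off stays far below the 1e−9 oracle tolerance),
giving per-bp scores in a few vectorized passes instead of per-window
featurization. The score is assigned to the central base (position 74
of 147); the outer 73 bp and any window containing N are NaN. The
track is made *exactly* strand-symmetric by averaging the forward pass
with the reversed pass over the reverse complement — mathematically a
no-op, numerically it removes the ~1e−13 summation-order asymmetry.

The packaged default model was trained on a synthetic sequence-driven
occupancy track (`sequence_driven_dataset(seed=42, scale=0.4)`, 8000
sampled positions); its JSON metadata marks it as synthetic. It is a
working default for demonstrations, not a substitute for training on a
measured track of interest (`train_on_track`, `hmrnuc inos-train`).

## Profiles and periodicity

Metaprofiles accumulate track values at anchor + offset with per-offset
counts; offsets beyond the track are masked, never zero-filled, so
means stay unbiased near edges. By default 3′-side anchors are mirrored
(offset → −offset) so "into the methylated flank" points the same way
for both sides and the two boundary sets pool; the unmirrored
orientation is the 5′-anchor convention. Heatmap matrices are one
masked row per interval anchored at the chosen boundary, sorted by
interval length. The phasing period is the lag of the maximum of the
mean-subtracted, variance-normalized autocorrelation within 120–260 bp
(the plausible nucleosome-repeat range); an optional permutation null
(shuffling profile values) gives a 95th-percentile significance line
for the prominence. Autocorrelation was preferred to spectral fitting
because profiles here are a few thousand points with a strong
non-periodic trend, where a windowed autocorrelation maximum is robust.

## Cross-tissue comparison

"Common" HMRs are one-to-one matches with reciprocal overlap ≥ 50% of
each region (greedy by largest shared span, ties to the leftmost
partner — validated against exhaustive matching on small sets);
everything unmatched is tissue-specific. CGI overlap is ≥1 bp. Extended
pairs are overlapping cross-set pairs whose boundary anchors match
exactly on one side (tolerance 0 by default, exposed because methylome
noise can shift the first CpG) and differ on the other; the shared end
is boundary 1, the short cell's far end boundary 2, the long cell's
boundary 3. TSS proximity classifies each HMR as containing a TSS,
within 2 kb of one, or distal.

## Boundary sequence features

Peak scores are means over ±73 bp (one nucleosome half-length) around
each boundary, masked at track edges; strata cut the score distribution
at its 20th/80th percentiles with ties resolved by input order. The
k-mer table takes the 6-mer placing the boundary CG at positions 3–4,
reverse-complementing 3′-side windows so the CG reads consistently;
non-CG boundaries and windows off the chromosome are skipped and
reported. Enrichment is log2 of stratum frequencies with a
one-pseudocount-equivalent epsilon per set. The observed/expected
analysis walks genomic CG sites outward (negative indices) and inward
(positive) from the boundary CpG; "expected" is the genome-wide
frequency over all CG-centered windows — a declared choice; a
flank-local or composition-matched baseline would be alternatives.
AUC uses the midrank Mann–Whitney statistic (invariant under monotone
transforms); ROC points are emitted at every distinct threshold. The
CG-indicator predictor is the binary presence of a CG at the evaluated
boundary position — deliberately the weakest sequence predictor, and
since first-unmeth anchors sit on CGs it is essentially uninformative
(AUC ≈ 0.5), which is exactly the point of the comparison.

## Synthetic study conditions

`simulate_genome` draws i.i.d. bases at background GC 0.42 with
non-overlapping 1-kb islands at GC 0.65 (CGIs); island CpG density is
~2.4× background from composition alone. The default 5-Mb genome
carries ~220k CpGs.

`simulate_methylome` plants 300 common HMRs (36.3% of the common loci
centered on CGIs), 100 tissue-specific per cell and 100 extended pairs
(lengths uniform 500–2500 bp, extensions uniform 100–460 bp, mean 280),
then edits the genome so the boundary geometry is exactly controllable:
a CG is forced at each planted boundary, CpGs within a drawn gap
(uniform 100–200 bp, mean 150) are cleared and a methylated CpG is
forced exactly at the drawn distance. Extended pairs share the
boundary-1 CpG exactly; the short cell's far side gets no carved gap
because the extension region must keep its CpGs for the long cell —
so measured gap means on datasets containing extended pairs run
slightly below 150 (the acceptance run reports ~141), while the
dedicated common-only recovery lands on the planted 150 ± 10. Counts
are beta-binomial around state means 0.05/0.85 (dispersion 0.1) at
Poisson(20) coverage; zero-coverage CpGs are unobserved.

`simulate_fragments` draws midpoints from a mixture of genome-wide
background and Gaussian-jittered (σ = 20 bp) nucleosome positions at
boundary + k·165 bp (k = 0..2) into the methylated flank, amplitudes
decaying 0.7 per step and calibrated so the k = 0 peak is 3× the local
background. Insert lengths are N(147, 10²), rounded and truncated to
[50, 300] so the 100–160 filter has work to do. Two knobs make
occupancy sequence-driven: `sequence_bias` tilts the background toward
GC-rich 147-bp windows (∝ exp(bias·z)), and `gc_coupling` scales each
boundary's amplitude with its window-GC z-score, clipped to |z| ≤ 2 so
no single anchor dominates pooled averages. `motif_boost` multiplies
the amplitude at boundaries carrying a planted E-box.

`plant_motifs` writes CACGTG centered on boundary CpGs and at
background CpG sites. Boundaries carry the motif at rate
max(boundary_fraction, background_rate): with no preferential planting
boundaries look exactly like background (obs/exp ≈ 1), and with
boundary_fraction = 0.2 over background 0.1 the boundary ratio is ≈ 2.
Edits can destroy CpGs adjacent to a planted window, so the one-call
generator re-derives methylome records and truth CpG sets from the
final sequence.

Two named condition sets are used throughout:

- `paperlike_dataset` — homogeneous boundary amplitudes. Used for HMR
  recovery, boundary-profile peak/period and gap statistics, where
  pooled averages should reflect every boundary equally.
- `sequence_driven_dataset` — sequence_bias 1.5, gc_coupling 1.2,
  motif_boost 6. Used for the predictor-AUC ordering and the
  top-vs-bottom 6-mer ranking, which are statements *about*
  sequence-driven occupancy. The couplings are moderate-to-strong by
  design: at desk scale (≈200 boundaries per stratum) a weak coupling
  leaves the 6-mer ratio ranking at the mercy of small-count noise
  (a 4-vs-0 k-mer outranks a genuine 80-vs-17 enrichment), which is a
  sample-size artifact, not a biology switch.

Everything is driven by `numpy.random.Generator` seeds; one integer
reproduces a dataset byte-identically, and `simulate_dataset` derives
sub-seeds (< 2³¹) for genome, methylome, motifs and fragments.

What the generator does **not** emulate: MNase sequence bias and
digestion-level effects, duplicate reads, distance-dependent
methylation transitions, realistic CpG depletion of the background
genome (i.i.d. composition is CpG-rich relative to mammalian DNA),
chromatin beyond the planted boundary arrays, and any coupling between
expression and nucleosome organization. Passing tests therefore show
that the estimators recover what was planted under the stated noise
model — not that real tissue data would behave as cleanly.

## Problem sizes and runtime

Default conditions are a 5-Mb single-chromosome genome, ~220k CpGs per
methylome, 600 HMR loci and 500k fragments — the full pipeline runs in
well under a minute on one core, and the complete test suite plus the
acceptance script in a few minutes. These sizes were chosen as the
smallest at which every recovery statistic is comfortably away from its
noise floor (e.g. ~1000 boundary anchors give a clean 165-bp
autocorrelation peak and ±20 bp peak localization); the HMM
emission-recovery check refits 20 independent 10k-CpG chains.

## Known limitations

- Transitions ignore inter-CpG distance; HMR length calibration
  therefore differs from distance-aware callers on sparse-CpG genomes.
- The beta-binomial moment-matched M-step estimates dispersion less
  efficiently than a full digamma-based MLE; state means are accurate
  (the acceptance run measures median level error ~0.002) but α+β is
  biased at low coverage.
- The "common/tissue-specific" labels depend on the reciprocal-overlap
  threshold (default 50%, exposed); the extended-pair finder requires
  exact boundary-CpG identity by default and will miss pairs whose
  first CpG shifted under noise unless `identical_tol` is raised.
- The obs/exp "expected" baseline is genome-wide; composition-matched
  baselines would shift absolute ratios.
- INOS features stop at 4-mers, so a 6-bp motif is seen only through
  its constituent k-mers.
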