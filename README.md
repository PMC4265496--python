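# hmrnuc

Nucleosome organization at the boundaries of hypomethylated regions
(HMRs).

In mammalian genomes most CG dinucleotides are methylated; unmethylated
CpGs cluster into hypomethylated regions, inside CpG islands (CGIs) at
promoters and outside them at cell-type-specific enhancers. Where the
methylation state switches — the HMR boundary — nucleosomes tend to sit
in well-positioned, phased arrays that propagate into the methylated
flank, and at non-CGI boundaries this positioning is largely encoded in
the DNA sequence itself. `hmrnuc` is a pipeline for quantifying that
organization from MNase-seq fragment maps and whole-genome
bisulfite-style methylomes, for researchers in epigenomics and
regulatory genomics. Because the full analysis needs nothing beyond
fragment intervals, per-CpG counts and a genome sequence, the package
ships a synthetic-data module that generates all three with planted
ground truth, so every stage is testable end to end on a laptop.

## What it computes

- **Nucleosome occupancy tracks** — paired-end MNase fragments are
  size-selected to mononucleosome inserts (100–160 bp inclusive), each
  fragment is reduced to its midpoint (the dyad estimate,
  `floor((start + end − 1)/2)`), and the per-bp midpoint counts are
  convolved with a Gaussian kernel (σ = 20 bp, truncated at ±4σ) to
  give a continuous signal, optionally normalized to genome-wide mean 1.
- **HMR calling** — per-CpG counts *(m<sub>i</sub>, n<sub>i</sub>)* are
  modelled with a two-state HMM over CpG sites with beta-binomial
  emissions, `m_i | s_i ~ BetaBin(n_i, α_s, β_s)`, fitted by Baum–Welch
  (moment-matched emission updates, accepted only when they increase
  the expected complete-data likelihood, so the EM ascent property
  holds). HMRs are maximal runs of CpGs with posterior P(hypo) > 0.5,
  at least 4 CpGs, split across >10 kb CpG deserts. Boundaries can be
  anchored at the first or second unmethylated CpG or the adjacent
  methylated CpG.
- **Intrinsic nucleosome occupancy scores (INOS)** — every 147-bp
  window is summarized by reverse-complement-collapsed k-mer counts
  (k = 1..4, 180 features) plus GC fraction, and a Lasso linear model
  (cyclic coordinate descent, objective `½·MSE + λ‖w‖₁`) maps features
  to occupancy. Genome scoring assigns the prediction to the central
  base and is exactly strand-symmetric. The model is trainable against
  any measured track; a synthetic-trained default is packaged.
- **Boundary-anchored profiles** — metaprofiles and length-sorted
  heatmap matrices around boundary anchors with masked (not
  zero-filled) edges, and phasing-period estimation by mean-subtracted
  autocorrelation (search window 120–260 bp).
- **Cross-tissue HMR classes** — common vs tissue-specific labels by
  greedy one-to-one reciprocal-overlap matching, CGI/TSS overlap
  fractions, and extended-HMR pairs sharing one boundary (boundary 1)
  with a short (boundary 2) and an extended (boundary 3) end.
- **Sequence features at boundaries** — boundary nucleosome peak scores
  (±73 bp window means, stratified at the 20th/80th percentiles), 6-mer
  enrichment tables centered on the boundary CG, observed/expected
  positional ratios of the E-box motif CACGTG at CG indices −5..+5, and
  ROC/AUC (midrank Mann–Whitney) comparison of predictors such as INOS
  vs a bare CG indicator.

## Worked example

```python
import numpy as np
import hmrnuc as h

# generate a small synthetic dataset with planted ground truth
ds = h.synthetic_data.paperlike_dataset(seed=1, scale=0.2)  # 1 Mb genome

# call HMRs from the cell-a methylome
hmrs, fit = h.call_hmrs(ds.methylomes["a"], seed=1)
jac = h.recovery_jaccard(hmrs, ds.truth.hmrs["a"])
print(f"called {len(hmrs)} HMRs "
      f"(state levels {np.round(fit.params.expected_levels, 3)}, "
      f"median Jaccard vs planted truth {np.median(jac):.2f})")

# build the nucleosome occupancy track and the boundary metaprofile
kept, _ = h.filter_fragments(ds.fragments["a"])
counts = h.midpoint_counts(kept, chrom_length=len(ds.genome))
track = h.normalize_track(h.smooth_track(counts, sigma=20.0, chrom=ds.genome.chrom))
profile = h.metaprofile(track, h.anchors_from_hmrs(hmrs), flank=2000)
period = h.estimate_periodicity(profile)
peak = int(profile.offsets[np.nanargmax(profile.mean)])
print(f"profile peak at {peak:+d} bp from the boundary CpG; "
      f"phasing period {period.period} bp (prominence {period.prominence:.2f})")

# E-box obs/expected ratio at the boundary CpG and 5 CpGs away
oe = h.obs_exp_positional(ds.genome, hmrs).set_index("cg_index")
print(f"CACGTG obs/exp: {oe.loc[0,'ratio']:.2f} at the boundary CG, "
      f"{oe.loc[5,'ratio']:.2f} five CGs inside")
```

Output:

```
called 100 HMRs (state levels [0.051 0.85 ], median Jaccard vs planted truth 1.00)
profile peak at -1 bp from the boundary CpG; phasing period 165 bp (prominence 0.56)
CACGTG obs/exp: 1.99 at the boundary CG, 0.87 five CGs inside
```

The caller recovers the planted regions essentially exactly (state
methylation levels 0.05/0.85, per-HMR CpG-set Jaccard 1.0), the
averaged occupancy peaks on the first unmethylated CpG with the planted
165-bp nucleosome repeat, and the E-box is found at twice its
genome-wide rate exactly at the boundary CG but nowhere nearby —
the planted 2-fold enrichment.

The same pipeline is available as a CLI (`hmrnuc simulate`, `hmrnuc
call-hmr`, `hmrnuc track`, `hmrnuc profile`, `hmrnuc compare`, `hmrnuc
motifs`, `hmrnuc inos-train`, `hmrnuc inos-score`, `hmrnuc convert`,
`hmrnuc validate`) operating on FASTA, BED/bedGraph and the 6-column
methylome TSV dialect (chrom, pos, strand, context, level, coverage;
0-based positions, `--one-based-meth` converts 1-based dialects).

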