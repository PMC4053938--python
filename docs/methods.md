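# Methods

This note documents the models, parameter choices and numerical decisions
behind bivalentscope, and what the synthetic fixture does and does not
establish about real sequencing data.

## Coordinate conventions

All coordinates are 0-based, half-open (BED convention): an interval
`[start, end)` has length `end − start`, and two intervals that merely touch
do not overlap. The TSS of a plus-strand gene is `start`; for a minus-strand
gene it is `end − 1`, the last covered base, so that a gene and its
base-level mirror image have mirrored TSSs. The promoter window follows the
same logic: on `+` it is `[tss − up, tss + down)`, on `−` it is the exact
reflection `[tss − down + 1, tss + up + 1)`. This makes every profile
operation equivariant under mirroring the genome (tested as an invariant).

bedGraph input with overlapping runs is rejected rather than summed: the
track is then a well-defined function of position and total signal is a
simple sum over runs. Queries on chromosomes absent from a track return
zeros with a logged warning so partial fixtures still run.

## Profile matrices

`build_tss_matrix` bins mean per-bp signal into fixed-width bins over
tss ± flank; minus-strand rows are computed directly in transcript
orientation (bin `[d, d+w)` of a minus-strand gene reads genome bases
`[tss − d − w + 1, tss − d + 1)`), so the shared axis is always 5′→3′.
Row values are means, not sums, so bins of unequal width stay comparable.
Defaults: 50 bp bins for ±5 kb windows (200 bins) and 25 bp for ±2 kb.
The scaled gene-body mode maps each gene body onto 100 equal fractions
(fractional-overlap weighting for genes shorter than the bin count, which
are flagged) between fixed-bp flanks; its composite axis uses negative bp
upstream, 0–1000 per-mille-of-gene inside the body, and 1000+bp downstream.

`compare_profiles` tests a per-bin condition difference with a paired
label-swap permutation: for each gene the control/treatment rows are
swapped with probability ½, giving the exact null for symmetric per-gene
differences. Two-sided p-values use `(b + 1)/(n_perm + 1)` smoothing
(default 1000 permutations, seeded).

## Classification rules

* Expression tiers at RPKM 0.1 and 5 (left-closed: exactly 0.1 is "low",
  exactly 5 is "medium/high").
* Tissue-specific genes: RPKM ≥ 10 in the target sample and < 1 in every
  other sample. Housekeeping genes: RPKM > 10 in all samples.
* CpG classes on 500-bp windows slid at 1 bp over the promoter sequence
  (tss ± 1 kb): HCP if any window has CpG observed/expected ratio
  `#CG·L/(#C·#G)` > 0.75 **and** GC fraction > 0.55; LCP if no window
  reaches ratio 0.48; ICP otherwise. A CG dinucleotide counts in a window
  only when both bases lie inside it, which keeps the classification
  invariant under reverse complement (a tested property).
* Chromatin classes by ≥ 1 bp peak overlap with tss ± 1 kb: K4, K27,
  K4/K27 (bivalent), none. No peak-score cutoffs are applied.
* Enhancers are assumed pre-filtered to H3K4me1-positive distal elements;
  this package only splits them into active (H3K27ac-overlapping) vs poised.

## Co-occupancy statistics

Density of a mark over an element class is covered bp / total bp of the
merged elements (a fraction in [0, 1]); splitting a mark interval into
adjacent pieces cannot change it. The enrichment test between two disjoint
element classes reassigns elements between the classes preserving sizes.
When the number of distinct reassignments C(n, n_A) does not exceed the
permutation budget the null is enumerated exhaustively and the p-value is
the exact tail fraction (identity included); otherwise the null is sampled
with a seeded generator and smoothed as above. Classes whose universes
overlap are rejected — each element must belong to exactly one class.
Families of p-values emitted by the pipeline are Benjamini–Hochberg
adjusted and reported alongside the raw values.

Overlap fractions count each source interval once, hit if it shares ≥ 1 bp
with any target interval. Mark correlation matrices use per-region mean
signal for tracks and binary occupancy for peak sets; a zero-variance
vector yields NaN correlations with a warning rather than an error.

## Correlation-distance k-means

Profiles are clustered under d(a, b) = 1 − PearsonR(a, b), which makes
membership invariant to per-row scale and offset, so no further row
standardization is applied. Rows that are constant up to float rounding
have no defined correlation and are excluded up front (logged). One
numerical subtlety: the reported centroids are per-bin means of the raw
member profiles, but the *assignment* step correlates rows against the mean
of the row-standardized members. The standardized mean maximizes the summed
correlation of members to their center, which guarantees the objective
Σ(1 − r) is non-increasing every iteration; raw-mean centers do not. An
emptied cluster is re-seeded from the worst-fit point. Runs are
deterministic given the seed; stability across restarts is summarized by
the mean pairwise adjusted Rand index (label-permutation invariant) over
100 consecutive seeds.

## Two-Gaussian decomposition

The aggregate TSS profile is modelled as
`A·[w·exp(−(x−μ₁)²/2σ₁²) + (1−w)·exp(−(x−μ₂)²/2σ₂²)]` and fitted by
bounded least squares (trust-region reflective, analytic Jacobian, xtol =
ftol = gtol = 5e−16 so that shift/rescale equivariance holds to ~1e−7).
Twelve starts are tried: candidate mean pairs from the two strongest local
maxima of a lightly smoothed profile and from the axis quartiles, σ at
0.02×, 0.1× and 0.3× the axis span, w ∈ {0.3, 0.5}; the best RSS wins.
The 0.02× σ start matters: on a ±5 kb axis the coarser starts are
1000–3000 bp wide and the optimizer can drop a genuinely narrow (~80 bp)
component into the weight floor. σ is bounded below at bin_width/2 to
prevent collapse onto a single bin. The model is symmetric under swapping
the components together with w ↔ 1 − w, so components are reordered
post-hoc to enforce μ₁ ≤ μ₂. The fit is performed on the TSS ± 5 kb
metaprofile, the window on which the aggregate curve is constructed.

A caution from the degenerate-baseline experiments: if a profile carries a
constant positive offset (e.g. clipped noise far from the peaks), one
component can widen into a baseline absorber. Aggregate profiles built
from signal-supported noise do not show this.

## Synthetic data: what it emulates

The generator plants, on one synthetic chromosome (default 400
non-overlapping genes of 2–12 kb, mixed strands, 2–8 exons, ≥ 14 kb gaps so
±5 kb windows never collide):

* **Bivalent promoters (30%)**: Tet1 = two Gaussians at μ₁ = −39 bp
  (σ 80) and μ₂ = +455 bp (σ 400), w = 0.4, A = 1 — the downstream
  component broad, as expected for spreading PRC2-recruited binding; 5hmC
  coincident with the downstream component only; a broad H3K27me3 block
  over −500..+2500 bp; Suz12 peaks downstream (+100..+800); K4me3 and
  Sin3a peaks at the TSS. The paper-scale centers (−39/+455) are used as
  the planted truth so the synthetic pipeline mirrors the real geometry;
  the widths are this package's choice since no widths are printed
  anywhere.
* **K4-only promoters (50%)**: a single TSS-centered Tet1 Gaussian
  (σ 150), no H3K27me3, no promoter 5hmC.
* **Silent promoters (20%)**: no Tet1; Sin3a on 70% of them; 15% carry
  PRC2 without Tet1. Together with ~200 Tet1-free distal Sin3a sites this
  reproduces the qualitative co-binding picture: most Suz12 sites, but
  only about half of Sin3a sites, fall inside Tet1 peaks.
* **Gene-body 5hmC** rises and falls with expression:
  density = 0.5·exp(−(log₁₀RPKM − 1)²/(2·0.8²)), peaking at log₁₀RPKM = 1
  and vanishing for silent and very highly expressed genes, with exons
  boosted 1.5× over introns.
* **Expression** is log₁₀-normal per tier (means −3 / 0.5 / 1.5, sd 0.6,
  truncated to the tier's RPKM range) across four samples; 8% of K4-only
  genes are housekeeping (> 10 RPKM everywhere) and 15% of bivalent genes
  are liver-specific (≥ 10 in liver, < 1 elsewhere) — developmental genes
  silent in the stem-cell-like sample.
* **Promoter sequences** (2 kb) are drawn i.i.d. at class-specific GC
  (0.60/0.50/0.40 for HCP/ICP/LCP targets) with CpG dinucleotides retained
  at rates 1.0/0.6/0.15, which lands ≥ 95% of promoters in their intended
  class under the classifier.
* **Knockdown**: a second 5hmC track with the bivalent downstream
  component halved, leaving gene bodies and K4-only genes untouched.

Signal is piecewise-constant at 10 bp resolution with Gaussian noise
(sd = 10% of the component amplitude) added only where the deterministic
signal lives, clipped at zero. Peak calls are a thresholding stand-in
(> 25% of the track's reference amplitude over ≥ 50 bp); real peak calling
is out of scope. All randomness flows through one seeded generator and all
coordinates sit on integer grids, so regeneration is byte-identical.

What passing tests on this fixture do **not** show: robustness to read
sampling noise, mappability artifacts, copy-number and GC biases,
overlapping transcripts, inter-gene signal bleed, or mis-annotation —
real tracks are far less clean than piecewise-constant Gaussians. The
fixture establishes that the estimators are correct and well-calibrated on
data satisfying their assumptions, with effect geometry and sizes in the
biologically reported range.

## Problem sizes

Defaults were chosen so the whole stack runs comfortably on a laptop core:
400 genes on a 12 Mb chromosome, 200-bin profiles, 999 permutations,
100 clustering restarts, 100 Monte-Carlo fit replicates. The full pipeline
over the default fixture takes a few seconds; the complete test suite
(including 100-replicate recovery and type-I calibration) about a minute.

## Known limitations

* One chromosome; multi-chromosome inputs are supported by the readers and
  track queries but the generator emits a single one.
* The enrichment test conditions on the observed mark track (elements are
  permuted, marks fixed); no GC- or mappability-matched genomic background
  model is provided.
* The two-Gaussian fit assumes exactly two components; model selection
  over component count is out of scope.
* `evaluate_bimodal`'s weight is constrained to the open interval (0, 1);
  a pure single-Gaussian is represented by w → 1 within float precision.
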