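# bivalentscope

Downstream analysis of genome-wide 5-hydroxymethylcytosine (5hmC), Tet1 and
Polycomb (PRC2) occupancy around gene promoters, built as a reusable Python
library plus a set of narrative analysis scripts.

In mouse embryonic stem cells, many developmental genes carry *bivalent*
promoters marked by both H3K4me3 (active) and H3K27me3 (repressive). Tet1,
the enzyme that oxidizes 5-methylcytosine to 5hmC, binds these promoters in
two distinct pools: a narrow peak essentially on the transcription start
site (TSS), and a broad peak centered a few hundred bp downstream that
coincides with PRC2 (Suz12/Ezh2) and with 5hmC itself. This package
implements the quantitative machinery needed to see that structure:

- **Metagene profiles** — genes × position matrices of binned signal around
  the TSS or over length-normalized gene bodies, with strand-aware axes,
  row orderings (by expression, by H3K27me3 level) and subset metaprofiles.
- **Promoter classification** — expression tiers from RPKM (no / low /
  medium-high at 0.1 and 5), tissue-specific and housekeeping gene
  selection, CpG-content classes (LCP/ICP/HCP from windowed CpG
  observed/expected ratio and GC fraction), chromatin classes (K4, K27,
  bivalent K4/K27) and active/poised enhancer states.
- **Co-occupancy statistics** — covered-bp densities of a mark over element
  classes with permutation enrichment tests (exhaustive when the
  reassignment space is small, seeded Monte Carlo otherwise), peak overlap
  fractions, and promoter-level mark correlation matrices.
- **Profile decomposition** — the two bespoke numerics: k-means clustering
  of per-gene binding profiles under Pearson correlation distance
  d = 1 − r with multi-restart stability (adjusted Rand index), and a
  six-parameter least-squares decomposition of an aggregate TSS profile
  into two non-normalized Gaussians,

  ```
  f(x) = A · [ w · exp(−(x−μ₁)²/2σ₁²) + (1−w) · exp(−(x−μ₂)²/2σ₂²) ]
  ```

- **Synthetic data** — a deterministic generator producing a ground-truthed
  chromosome (BED12 genes, bedGraph tracks, BED peaks, promoter FASTA,
  RPKM tables) whose planted structure mirrors the biology above, so every
  stage is testable without sequencing data.

## Worked example

The analysis scripts run the pipeline over the default synthetic fixture:

```bash
python analysis/01_simulate.py                # writes results/fixture/
python analysis/05_cooccupancy_clustering.py  # overlap, clustering, fit
```

which prints (numbers from an actual run):

```
suz12: 90.9% of 132 sites also bound by Tet1
sin3a: 55.6% of 576 sites also bound by Tet1
cluster sizes: {1: 200, 0: 120}
stability over 100 restarts: mean ARI = 1.000
two-Gaussian fit over 120 bivalent promoters: narrow component at -39 bp
(sigma 73), broad component at +442 bp (sigma 427), weight 0.39
```

Reading this: most Suz12 (PRC2) sites but only about half of Sin3a sites
sit inside Tet1 peaks; k-means with correlation distance splits the 320
Tet1-bound promoters into the 200 K4-only genes (TSS-centered profile) and
the 120 bivalent genes (downstream-shifted broad profile), perfectly stably
across 100 random restarts; and the bivalent-promoter Tet1 metaprofile
decomposes into a narrow component just upstream of the TSS and a broad
component several hundred bp downstream — the generator plants these at
−39 bp and +455 bp, and the fit recovers them from the noisy tracks.

The remaining scripts (`02`–`04`, `06`) cover expression-ordered heatmap
matrices and gene-body density, element-class densities with enrichment
tests and the mark correlation matrix, H3K27me3-ordered profile matrices,
and the control-vs-knockdown differential metaprofile in which 5hmC is lost
specifically from the downstream component.

As a library:

```python
from bivalentscope.synthetic_data import SimConfig, generate_annotation, generate_tracks
from bivalentscope.profile_engine import build_tss_matrix, mean_profile
from bivalentscope.profile_decomposition import fit_two_gaussians

cfg = SimConfig(seed=1)
ann = generate_annotation(cfg)
data = generate_tracks(ann, cfg)
bivalent = data.truth.index[data.truth.gene_class == "bivalent"]
matrix = build_tss_matrix(data.tracks["tet1"], ann.genes, flank=5000, bin_width=50)
fit = fit_two_gaussians(mean_profile(matrix, bivalent))
print(round(fit.mu1), round(fit.mu2))   # -> -39 442
```

## Layout

```
src/bivalentscope/        the library (all computation lives here)
  genomic_core.py         domain types + BED/BED12/bedGraph/FASTA/TSV I/O
  profile_engine.py       profile matrices, metaprofiles, differentials
  feature_classify.py     expression / CpG / chromatin / enhancer classes
  cooccupancy.py          densities, enrichment tests, overlaps, correlations
  profile_decomposition.py  correlation k-means + two-Gaussian fit
  synthetic_data.py       ground-truthed fixture generator
  pipeline.py             figure-level orchestration (RunConfig -> outputs)
analysis/                 numbered narrative drivers over the library
scripts/acceptance.py     end-to-end recomputation of headline numbers
docs/methods.md           model, parameters, and numerical choices
tests/                    pytest suite (unit, property, acceptance)
```
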