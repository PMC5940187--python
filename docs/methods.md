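# Methods

## Scope and data model

`gbrkit` operates on *called peaks* and *per-region read counts*, not on raw
reads: peak calling, alignment, and IDR model fitting are upstream of the
package. All coordinates are 0-based half-open (BED convention); a peak may
carry a summit as an offset from its start (`-1` = unknown, midpoint
fallback). Half-open adjacency is never overlap; the default overlap
criterion everywhere is ≥ 1 bp, configurable per call (`min_bp`).

## Interval operations

**Venn partitioning.** Peaks are merged within each input set, the pooled
intervals are flattened into connected union regions, and each region
receives exactly one signature — the subset of inputs overlapping it by
≥ `min_bp` bp (a peak shorter than `min_bp` counts when fully contained).
Counting atomic union regions, rather than input peaks, means several peaks
of one set falling in one region count once; compartment counts are then
consistent with per-set totals whenever overlaps are one-to-one, which is
the regime peak data occupy.

**Reproducibility filter.** The irreproducible-discovery-rate machinery is
replaced by a deterministic replicate-overlap filter: union regions of the
pooled replicate calls supported by every replicate. This is intentionally
simple — it keeps the "reproducible set" concept while staying fully
auditable.

**Consensus regions.** Pooled per-sample intervals are segmented at every
breakpoint; segments supported by ≥ `min_samples` (default 2) samples are
kept, contiguous kept segments are fused, and the region summit is the
support-weighted centroid — the balance point of per-base sample support.

## Differential occupancy

Counts are normalized to a common (mean) library size. For contrast
condition A over reference B, per-region group means m_A, m_B and variances
feed a pooled method-of-moments dispersion estimate
α̂ = (s²_A − m_A + s²_B − m_B) / (m_A² + m_B²), clipped to [0, 10]. A
mean–dispersion trend (bin means of α̂ over ~20 quantile bins of the overall
mean, linearly interpolated in log-mean) regularizes the per-region
estimates: α* = ½ α̂ + ½ trend. Bin *means* (not medians) are used because
the MoM estimator is roughly unbiased but extremely noisy at n = 2, and the
median of its sampling distribution sits well below the truth — a median
trend would systematically understate dispersion and inflate significance.

The Wald statistic is log2((m_A + c)/(m_B + c)) over its delta-method
standard error with NB variance μ + α*μ² evaluated at the group means
(pseudocount c = 0.5), two-sided normal p, Benjamini–Hochberg correction
across regions. Significance gating: FDR ≤ α (default 0.01) and
|log2FC| ≥ log2(min_fold) (default 3; `min_fold = 1` disables the gate, as
used for the remodeler contrasts).

This is deliberately lighter than a full empirical-Bayes GLM: at two
replicates per condition, the paper's design, the moment estimator plus
trend shrinkage is stable, and in all-null simulations (20 × 2000 regions,
n = 2/group) the BH-gated rejection fraction stays two orders of magnitude
below the nominal 0.01 (the raw Wald tail is mildly anticonservative at
n = 2, which the fold gate and BH step absorb; the acceptance suite measures
this). Fold-change recovery is unbiased: median estimated log2FC at planted
8-fold regions is within 0.02 of log2 8.

Library-size normalization is total-count (CPM), not median-of-ratios:
regions are near-constant width and the synthetic libraries are balanced;
the normalization is configurable through the library_size column of the
samples sheet.

## Classification

Labels over consensus regions, assigned in priority order (mutually
exclusive, exhaustive):

| label | definition |
|---|---|
| `blocked` | significant gain upon depletion ∧ in depleted-cell reproducible set (subtype `depletion_only` vs `shared_but_differential` by control-set membership) |
| `hic5_dependent` | in control reproducible set only |
| `non_blocked` | in both reproducible sets ∧ not significant |
| `shared_nonsig` | in depleted set only ∧ not significant |
| `other` | significant but absent from the depleted reproducible set, or in neither set |

The `shared_nonsig`/`other` split for the residual cases was an open design
point; the assignment above keeps every case a region can occupy nameable
and keeps `blocked`/`non_blocked` exactly as defined.

**Remodeler dependency.** Peak-presence route: a region is CHD9-dependent
iff it overlaps no called peak in the CHD9+coregulator co-depletion
condition (and analogously BRM). The pipeline overlaps against the *pooled*
replicate calls of the co-depletion condition rather than the
reproducibility-filtered set: a peak called in either replicate evidences
retained occupancy, whereas requiring reproducibility would count replicate
dropout as dependency and bias the percentages upward. Differential route: a
region is dependent iff the co-depletion-versus-single-depletion contrast is
significant (FDR ≤ 0.01, no fold gate) *and* the change is a reduction
(log2FC < 0). Percentages are rounded half-up to integers for report parity.

## Proximity, accessibility, motifs

**TSS windows.** Distance is summit-to-TSS, strand-agnostic, absolute. A
region belongs to a gene class if any TSS of that class lies within the
window; a region may belong to several classes (classes are tallied
independently) but counts once per class. Ratios of blocked to non-blocked
regions near each class are compared to the *block*-class ratio by Pearson
χ² (1 df, no continuity correction by default; Yates available).

**Accessibility.** "Open" is overlap with a called ATAC peak, not a coverage
threshold. Metaprofiles bin per-base coverage into 10-bp bins over
[summit−1 kb, summit+1 kb), scale by 10⁶/library, and average region-wise;
windows truncated at a chromosome start are zero-padded with a warning. Bins
are genome-ordered (regions are unstranded). The y-quantity is RPM per
10 nt; the source material labels the same profile RPKM in one place and RPM
in another — RPM is implemented.

**Motifs.** The bundled GRE (15 nt, GGTACAnnnTGTTCT with a free 3-nt
spacer), AP-1 (11 nt, TGACTCA core with soft flanks), and ETS (10 nt,
ACAGGAAGTG) models are curated stand-ins built from the field's consensus
sequences — the data file marks them as such, and which ETS-family member
the motif belongs to is deliberately left open. Scanning is log-odds against
a uniform background on both strands; `N` scores −∞; the default threshold
is 80% of each PWM's maximum score, which for these sharp matrices admits
the consensus (plus one soft-flank mismatch for AP-1) and keeps the
per-window false-positive rate of random sequence below ~0.5%. A region
counts once for prevalence regardless of hit multiplicity; positional
summaries use each region's best hit. Enrichment of a foreground class
against a background class is the hypergeometric upper tail on with-motif
counts. Offsets are measured hit-center to window-center in half-base units
so that reverse-complementing a window exactly negates them.

## Synthetic data generator

The generator plants, per region, everything the analysis is meant to
recover; defaults encode the study conditions.

- **Scale**: 4 × 30 Mb chromosomes, 5,000 requested regions (400 bp wide,
  ≥ 3 kb apart; candidates violating spacing are thinned label-blind, so
  ≈4,200 regions are emitted), gene classes of 534 *block* / 105 *ind* /
  364 *mod* genes ≥ 25 kb apart. The scale is a desk-scale choice: large
  enough that every recovered percentage has sub-point sampling error,
  small enough that a full run takes ~20 s.
- **Placement**: Poisson(2) regions within ±8 kb of each gene TSS, blocked
  with class probability 0.67 / 0.39 / 0.44 (*block*/*ind*/*mod*); remaining
  regions uniform but kept ≥ 12 kb from every TSS so the innermost window's
  proportions are planted cleanly (background blocked probability 0.55).
  Wider windows accumulate background, producing the dilution the 1 Mb
  window is expected to show.
- **Conditions**: six siRNA conditions × 2 replicates. Blocked regions are
  called only upon depletion (10% also called in control: the
  shared-but-differential subtype); co-depletion presence follows planted
  joint dependency categories — blocked (both 0.68, CHD9-only 0.12,
  BRM-only 0.04, neither 0.16), non-blocked (0.13/0.22/0.03/0.62).
  Replicate calls drop out independently at 2.5% with ±30 bp coordinate
  jitter, so the reproducibility filter is non-trivially exercised while a
  true blocked region is lost from its reproducible set only ~5% of the
  time.
- **Counts**: NB with dispersion 0.05; occupied level 300 expected counts
  (library 2×10⁷), blocked regions at 300/8 in coregulator-containing
  conditions (planted fold change 8), remodeler-dependent regions at 20% of
  the occupied level upon co-depletion.
- **ATAC**: open-in-control probability 0.25 (blocked) vs 0.70
  (non-blocked); depletion newly opens 15%/22% of blocked (ethanol/hormone)
  vs 8%/13% of non-blocked, monotonically (nothing closes). Coverage is
  Poisson around a Gaussian summit bump whose amplitude, per label ×
  condition, encodes the directional structure: blocked regions gain a
  hormone response only after depletion, non-blocked respond in both; the
  coverage tracks span only the ±1 kb analysis windows, so RPM scaling uses
  a fixed nominal library size rather than the emitted-signal sum.
- **Motifs**: 1-kb windows of uniform-random sequence; consensus instances
  planted on a random strand at prevalence GRE 0.44 / ETS 0.52 / AP-1 0.32
  in blocked vs 0.50 / 0.03 / 0.32 in non-blocked, at center-concentrated
  offsets (normal SD 60 / 140 / 220 bp respectively), re-drawn on collision
  with an earlier instance. Motif presence is planted independently per
  motif, so the any-motif fraction among blocked runs ≈82% rather than the
  ~77% a correlated design would give — co-occurrence assertions are
  therefore structural (union bound, subset conditionals), not calibrated
  to a joint distribution.

A single seed drives everything through per-component spawned streams, so
adding a component does not perturb the others and equal seeds give
byte-identical output bundles.

### What the generator does and does not emulate

It reproduces the *statistical skeleton* of the experiment: condition
design, reproducibility filtering, NB counts with realistic dispersion,
class-conditional proximity/accessibility/motif structure. It does not
emulate read-level artifacts (GC bias, duplicates, fragment-length effects),
peak-caller behavior (width/score distributions, sub-threshold signal
bleeding into neighbors), correlated motif co-occurrence, enhancer–gene
assignment beyond distance, or chromatin-domain structure. Passing recovery
tests therefore demonstrates that the pipeline's inference is correct under
its own model assumptions — not that those assumptions capture every
property of real chromatin data.

## Numerical choices and degenerate inputs

- Even-length interval midpoints floor: `(start + end) // 2`.
- Percentages round half-up (`decimal.ROUND_HALF_UP`).
- χ² with any zero margin raises; proportion-table rows for classes with no
  genes or no nearby regions are flagged undefined rather than erroring.
- Zero library sizes, empty region sets for open-fraction or profile
  aggregation, and significant ids absent from the consensus all raise.
- Profile windows clipped at a chromosome start are zero-padded (warned).
- All pipeline outputs are written with fixed precision ("%.6g") so reruns
  diff clean; rerunning on the same inputs is byte-identical.

## Known limitations

- The NB test is a moment/Wald approximation, not a GLM with shrunken fold
  changes; at n = 2 its raw p-values are mildly anticonservative in the
  extreme tail, mitigated in practice by the fold gate and BH step (measured
  in the acceptance suite).
- The published compartment counts imply two percentages (43% CHD9-dependent
  of 3,102 blocked by the differential route; 13% both-dependent of 2,156
  non-blocked by the peak-set route) that recompute to 42% and 12%; the
  package reports the recomputed values.
- Genome-wide totals from the original experiment (9,526 vs 2,553 regions,
  3,102 blocked, ATAC region counts) require the raw sequencing data and are
  exercised here only through their printed arithmetic and through synthetic
  recovery at reduced scale.
- Motif models are consensus-built stand-ins, not fitted matrices from a
  motif database; prevalence numbers on real sequence would depend on the
  exact matrices and thresholds used.
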