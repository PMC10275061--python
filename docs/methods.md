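# Methods

## Overview

`cmuscan` detects correlated methylation units (CMUs) by segmenting
per-window CpG correlation matrices as images, then quantifies how the
resulting units are shared across tissues, how they relate to genomic
features, and whether their internal correlation differs between groups.
This note records the model, the parameters that matter, the numerical
choices, what the synthetic data generator does and does not emulate, and
the known limitations.

## Preprocessing

Beta values (methylation fractions in [0,1]) are bounded and often
bimodal, which makes Pearson correlation sensitive to outliers and to
marginal shape. Each probe's sample distribution is therefore mapped to a
standard normal by the rank-based inverse-normal transform
`Φ⁻¹((r − 3/8)/(n + 1/4))` with ties averaged (Blom offset — standard and
well behaved in the tails; any monotone-equivalent variant gives the same
ranks, hence nearly the same correlations). Missing values stay missing;
probes with fewer than 3 observations are set entirely missing and
thereby excluded from correlation.

For group comparisons, transformed values are regressed on covariates
(intercept + expanded categorical indicators; OLS on complete cases per
probe) and the residuals carried forward, so subsequent correlations are
partial correlations. The order is transform → residualize.
Residualization is applied per group before group-specific correlation; a
pooled mode is available by passing the same covariate table to both
groups before splitting.

## Window tiling and correlation images

Chromosomes are tiled into non-overlapping windows of 250 kb anchored at
coordinate 0 (deterministic and genome-build independent; strong
inter-CpG correlation extends ~10 kb on average, so one window holds
several candidate units). Probe positions are 1-based manifest points;
the probe at position W exactly still falls in window 0 under the 0-based
half-open convention used for every emitted interval. Windows are hard
boundaries: cross-window units are not attempted, and the scan log flags
CMUs flush against a window edge.

Per window, Pearson correlations are computed pairwise-complete. Pairs
with fewer than `min_overlap = 30` shared samples and zero-variance
probes are set to r = 0 (not missing) and flagged, so the image stages
are total functions. The diagonal is forced to 1 and the matrix exactly
symmetrized.

## The image-clustering segmentation

1. **Smoothing.** 2-D convolution with a normalized, center-weighted box
   kernel, reflective borders; output re-symmetrized, clipped to [−1,1],
   diagonal restored. The default kernel is

   ```
   [[1, 1, 1],
    [1, 16, 1],
    [1, 1, 1]] / 24
   ```

   The center weight is deliberately heavy (2/3 of the mass). A block's
   outermost row/column mixes one side of the kernel with background
   zeros; with a softer kernel (e.g. a 3×3 binomial, center weight 1/4)
   an r ≈ 0.8 block's edge entries land at ≈ 0.75·r ≈ 0.6 — exactly at
   the default cutoff — so sampling noise makes the thresholded support
   ragged and fragments real blocks. With the default kernel edge entries
   sit at ≈ 0.87·r, comfortably above the cutoff, while an isolated noise
   pixel is still attenuated by a third, which at n ≥ 100 samples puts
   single-pair noise far below any sensible cutoff. The kernel is a
   parameter (`ICMParams.kernel`) for users who want stronger averaging.

2. **Cutoff.** Entries with |r| < α are zeroed; survivors keep their
   sign, because both positive and negative inter-unit correlation are
   unit-forming. Defaults: α = 0.6 within a cohort, 0.4 for cross-tissue
   scans (larger units that remain comparable across tissues). Raising α
   yields sub-units nested inside lower-α units.

3. **Edge detection.** Forward differences of the support indicator
   |T| > 0 along rows/columns, evaluated in a near-diagonal band
   (half-width 1, `ICMParams.edge_band`): any support transition between
   columns j and j+1 adjacent to the diagonal marks a cut at j+1. The
   narrow band keeps far-off-diagonal noise from cutting a genuine run.
   A probe exactly on an edge belongs to the left (lower-index) run.

4. **Unit calling.** A run between cuts is accepted as a contiguous CMU
   iff it has ≥ `min_cpgs` probes (default 4), its off-diagonal support
   density is ≥ `block_density` (default 0.9), and its mean |r| (zeros
   included) is ≥ α. The density+mean rule operationalizes "overall
   strong correlation even if not every pair is high": up to 10% of
   pairs may fall below the cutoff without rejecting the unit.

5. **Linking.** Two CMUs are linked when the mean |T| over their
   inter-block rectangle is ≥ α; connected components (transitive
   closure) with ≥ 2 members become non-contiguous CMUs. The pairwise
   sign is the sign of the signed rectangle mean. The linking statistic
   reuses α so that a single parameter governs "strong" throughout.

Window filters: `min_probes_per_window` = 4 (lenient) or 10 (stringent).

### Calibration properties (verified by the test suite)

- On exact block-diagonal images the segmentation equals an exhaustive
  maximal-interval search (200 random images, p ≤ 40).
- On the basic synthetic preset (20 blocks of 6–12 CpGs at within-r 0.8,
  n = 200, ~2000 probes), ≥ 95% of blocks are recovered at probe-set
  Jaccard ≥ 0.8 with ≤ 1 false call; measured 240/240 with 0 false calls
  over 12 generator seeds during development.
- Units called at higher α are probe-contained in units called at lower
  α on the same data (sub-CMU nesting).

## Asymmetric similarity

`Asy(S1, S2)` = fraction of S1's contiguous CMU regions sharing ≥ 1 bp
with any S2 region — a Tversky index with α=1, β=0. It is directional:
`Asy(S1,S2)=1` with `Asy(S2,S1)<1` means S1's units are a subset of a
richer S2 repertoire. The all-pairs matrix carries row/column medians and
a 1 − Pearson distance over score columns suitable for complete-linkage
clustering of datasets.

## Tissue-independent regions

One CMU set per unique tissue (when several datasets share a tissue, the
largest sample size wins; ties break lexicographically). Contiguous CMUs
are filtered to **strictly more than** `min_cpgs = 10` probes
(higher-confidence units), exclusion intervals (e.g. the HLA region) are
subtracted, and each tissue's intervals merged. Stacking all tissues and
taking maximal basepair runs with coverage depth **strictly greater
than** 0.8 × n_tissues implements the "largest region of overlap": at
n = 10 a region must appear in ≥ 9 tissues; 8/10 = 80% does not qualify.
Non-contiguous units contribute their span (first member start to last
member end) and require ≥ 3 member CMUs, which tolerates member-boundary
variation between tissues. No minimum length is imposed on a TI region
(1 bp suffices); callers can filter afterwards.

## Enrichment

- **Probe-based:** 2×2 Fisher exact (two-sided) on (in-CMU × in-feature)
  over all manifest probes; degenerate margins return p = 1 with a flag.
  An upper-tail hypergeometric variant `P(X ≥ k)` is also provided.
- **Region-based:** the observed score is the number of *distinct*
  feature intervals hit by the CMU set (an interval hit five times by
  five units scores five across the set, i.e. dedup by interval
  identity). For each observed CMU a random region of identical length
  is placed uniformly in a uniformly chosen window containing enough
  probes (≥ 4 lenient / ≥ 10 stringent — matching the windows the scan
  could have called units in, which compensates for the array's biased
  probe placement). The default 10,000 background sets' scores are
  modeled as a normal distribution; p is the upper-tail probability
  (one-sided, enrichment). Background sd = 0 returns p ∈ {0, 1} with a
  flag. A background region may fall in an observed CMU's own window.
  Type-I error at nominal 0.05 under a uniform-feature null is within
  [0.02, 0.09] (normal-approximation tolerance, verified at 200 runs ×
  1000 replicates).
- **Chromatin context:** %CpG overlap, %CMU overlap, %unique overlap
  (share of overlapping CMUs hitting exactly one interval), a hits-per-
  CMU histogram; the A/B compartment pair score
  `log(%CMU overlap / %CpG overlap)`; and a TAD containment fraction
  (spans fully inside a single TAD interval, i.e. not crossing a
  boundary).

## Differential correlation

Each group's residualized data defines its own CMUs (the collapsed list:
non-contiguous units replace their members). For each unit, paired
correlation matrices over the same probes are compared by:

- **Matrix test:** `χ² = Σ_{i<j} (z₁ᵢⱼ − z₂ᵢⱼ)² / (1/(n₁−3) + 1/(n₂−3))`,
  z = atanh(r) clipped at ±0.9999, df = p(p−1)/2. This is the
  independent-groups, Fisher-transformed chi-square for equality of two
  correlation matrices. It treats the off-diagonal z-differences as
  independent, which holds when inter-pair dependence is weak — exact
  for p = 2 (where it reduces to the two-sample Fisher-z test, verified
  to 1e−10) and calibrated under an independent-probe null (rejection
  0.049 at nominal 0.05 over 1000 replicates). Under strong within-unit
  correlation the statistic is anti-conservative; the both-tests rule
  below provides the guard.
- **Shifted rank-sum:** one-sided Mann-Whitney of the defining group's
  off-diagonal correlations against the other group's shifted up by
  μ = 0.1 — the defining group must be more correlated by at least μ, a
  deliberately coarse effect floor that also proxies for sample size
  (raise μ for small n). The correlation-matrix diagonal is identically
  1 and carries no information, so the test operates on off-diagonals.
  The reported effect size is the Hodges–Lehmann location shift of
  (other − defining): negative ⇒ the defining group is more strongly
  correlated.

Each test's p-values are Bonferroni-corrected within one family per
defining group ("per dataset"); a unit is significant only when **both**
corrected p-values are below 0.05. Power under the planted attenuation
scenario (within-r 0.8 → 0.4, n = 150/150) is ≥ 80% across 50 replicates
with the correct (negative, controls-defining) effect sign, and a null
split of one population yields ~0 hits.

## Synthetic data generator

The generator emulates exactly the structure the pipeline relies on: an
ordered manifest with jittered uniform probe spacing; a per-sample latent
multivariate normal with unit variance, `within_r` inside planted blocks,
signed `inter_r` between linked blocks (0 elsewhere); a logistic squash
into (0,1) around per-probe baselines. The logistic map is monotone, so
rank normalization recovers the latent correlation almost exactly — a
Beta-distribution copula would add realism of marginal shape but no new
information after rank-INT, which is why the simpler squash was chosen.
A requested covariance that is not positive definite (e.g. a frustrated
sign cycle) is repaired by eigenvalue clipping with re-normalized
diagonal, with a warning. Case/control pairs share everything except the
attenuated within-block correlation; optional shared covariate effects
are injected into the latent scale for residualization testing.

It does **not** emulate: probe-type chemistry differences, batch/plate
effects, cell-type mixture, distance-decaying background correlation, or
genuine biological boundary fuzziness. Passing tests therefore show that
the algorithm recovers the structure it defines under realistic sampling
noise — not that real tissues contain such structure.

Preset study conditions: `basic` (n = 200 samples, 20 blocks of 6–12
CpGs at within-r 0.8 among ~2000 probes on a 2.5 Mb chromosome),
`multitissue` (10 tissues, 12–16 CpG blocks shared by configurable
subsets, n = 100–150), `casecontrol` (n = 150 per group, one block
attenuated 0.8 → 0.4), `noncontiguous` (three 8-CpG blocks with the
middle one anti-correlated with both flanks).

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical outputs.
- Overlap means ≥ 1 shared basepair, everywhere.
- Single-probe intervals have length 1 bp ([pos−1, pos)).
- A kernel larger than the image is shrunk to fit (central part,
  renormalized) with a warning; all-zero images yield no edges and no
  units; empty CMU sets are errors where a ratio would be undefined
  (Asy's first argument) and 0 where a count is natural (second
  argument).
- Rank-sum with all values tied returns p = 1, effect 0, flagged.
- Bonferroni via statsmodels `multipletests`; Fisher/hypergeometric/
  rank-sum/normal/chi-square via scipy.stats; convolution via
  scipy.ndimage.

## Problem sizes in the test and acceptance runs

The bundled checks run the full pipeline at the preset conditions above:
1000 replicates for the matrix-test null, 50 power replicates, 200
enrichment null runs at 1000 background sets each (the production default
is 10,000), and 200 random images for the segmentation oracle. These
sizes give stable pass/fail behavior across seeds while keeping the whole
suite in the low minutes on a single CPU.

## Known limitations

- Windows are hard boundaries; a unit straddling a 250 kb edge is split
  (flagged in the scan log but not merged).
- The matrix test's independence assumption makes it anti-conservative
  inside strongly correlated units; it is never used alone.
- The region-based background matches genomic size but not local CpG
  density, and the probe-based test ignores spatial clustering — the two
  are complementary, as both can be inflated in opposite regimes.
- Genome build is carried as metadata only; no liftover.
- Sex chromosomes are excluded by design.
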