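# Methods

## Model and estimand

The analysis treats the per-region difference of group-mean cortical
thickness, ΔCT (group A minus group B, mm), as a response and the
column-standardized region × gene expression matrix X (R regions × G genes,
typically G ≫ R) as predictors. Partial least squares regression with a
single response (PLS1) extracts orthogonal latent components that maximize
covariance with ΔCT. The scientific object of interest is the first
component: its unit-norm gene weight vector has the closed form
w₁ ∝ Xᵀ(y − ȳ), i.e. the normalized vector of gene-wise covariances (for
standardized columns, correlations) with ΔCT. Subsequent components apply
the same rule to the X-deflated block; the response is never deflated,
which for a single response yields the identical sequence of weights. Each
score column is oriented so that its correlation with y is non-negative —
with w ∝ Xᵀy this holds by construction, and it fixes the meaning of
"positive weight" as higher expression where ΔCT is larger (regions thinner
in the converter-analogue group, under the stable-minus-converter
orientation). Variance explained is decomposed per component as the
incremental R² of y on the (orthogonal) scores, so the entries are
non-negative and sum to at most 1.

Treating positive-weighted genes as "transcriptionally upregulated" is an
interpretive convention of the field, not a computational claim; the
package only ever reports signed weights.

## Preprocessing contracts

Thickness tables must contain exactly two non-empty groups, no missing
cells and strictly positive values; violations are reported with the
offending subject/region. ΔCT is the difference of group means, so it is
invariant to subject order and to any constant added to all subjects.
Expression columns are z-scored with the sample (n−1) variance — documented
so that downstream z-scored weights are bit-reproducible — and zero-variance
genes are dropped with a logged warning. Expression and ΔCT are aligned on
the sorted intersection of region ids (never by file position); fewer than
10 shared regions is an error by default.

## Inference

**Component significance.** The fraction of ΔCT variance a component
explains is tested against refits on y permuted across regions
(n_perm = 10,000 at the paper-grade profile, 1,000 at the test profile),
with add-one smoothing: p = (1 + #{null ≥ observed})/(n_perm + 1), never
zero. For component 1 the permutation statistic has the closed form
‖g‖⁴/(‖Xg‖²‖y‖²) with g = Xᵀy_perm, which the implementation vectorizes
across permutations; a literal refit loop is used for later components and
as a regression check. The null permutes region labels only — it does not
preserve spatial autocorrelation (no spin test), so on strongly
autocorrelated maps the component p-value is anti-conservative; the
synthetic generator's AR(1) expression exercises exactly this regime.

**Gene-level inference.** Regions are resampled with replacement
(n_boot = 1,000 / 200 per profile), the model is refitted per resample
(columns re-centered), and each bootstrap weight vector is aligned to the
original component by its scalar projection — i.e. divided by w_b·w₀.
Dividing rather than sign-flipping matters: a unit-norm weight vector
estimated from a bootstrap resample carries roughly twice the noise mass of
the original direction when G ≫ R, which attenuates every bootstrap
coordinate by the cosine between the two directions (≈0.7 at 308 × 2000).
Sign-only alignment therefore understates the standard errors by the same
factor and inflates every z uniformly (measured null z s.d. ≈ 1.45, dozens
of false discoveries per null dataset); projection alignment restores a
null z s.d. of ≈ 1.0 and empirical false-discovery control. After
alignment, z = weight/SE with two-sided normal tails, BH q-values over all
genes, and the dual significance rule z > +1.96 (or < −1.96) *and*
q < 0.05. Resamples with a constant response or with no usable projection
are redrawn and logged.

**Spatial profile.** The component's regional score map (the centered
projection Xw) is averaged within each cytoarchitectonic class — the
default scheme is the five Von Economo classes plus limbic and insular
subtypes, but the class count follows the map file. Because scores are
centered, the permutation expectation of every class mean is exactly zero,
so the two-sided p-value counts permuted |class means| at least as large as
the observed one (add-one smoothed); direction is "over" when the observed
mean exceeds the null median; BH across classes. Class labels are permuted
jointly in each permutation, so the per-class nulls share draws; a
gene-resampling or spin-based null would be the natural alternative where
surface geometry is available.

**Gene-set overlap.** The significant gene list (union of up and down) is
overlapped with marker sets. The permutation null draws lists of the same
size uniformly without replacement from the universe, which *is* the
hypergeometric model, so both the Monte-Carlo and the exact upper-tail
p-value are reported (they agree within Monte-Carlo error by construction;
the permutation version is kept because it is what the methodology this
package operationalizes specifies). Tests are one-sided for enrichment.
The universe is the post-QC gene list of the analyzed expression matrix —
the frame the regression actually searched — not the genome.

## Synthetic data generator

The generator emulates the data shapes of a two-group imaging-transcriptomics
study and plants a signal that is exactly the estimand of PLS1:

* expression: each gene an independent AR(1) Gaussian process over the
  fixed region ordering, unit marginal variance, autocorrelation
  `expr_spatial_rho` (default 0.3 — regional expression maps are spatially
  smooth; an arbitrary ordering stands in for cortical geometry, which is
  out of scope);
* cohort: `n_causal` genes (default 50 of 2000) get N(0,1) weights; the
  planted pattern d is the standardized projection of expression onto
  those weights; group A subjects (default 100) are baseline 2.5 mm plus
  N(0, 0.1²) noise, group B subjects (default 40) additionally lose
  `effect_size × 0.1 mm` per standard unit of d (defaults 1.5 and 0.1 mm —
  a typical cortical-thickness effect magnitude), so ΔCT(A−B) tracks
  +effect_size·0.1·d;
* annotations: seven marker sets named after the canonical cortical cell
  classes, the first seeded with a controlled fraction of causal genes,
  plus a seven-class near-equal contiguous region partition.

What the generator does **not** emulate: cortical surface geometry and
geodesic autocorrelation, donor-level microarray noise, correlated gene
modules (genes are independent), or realistic per-region effect profiles
(none are published). Passing tests therefore demonstrate the statistical
machinery — calibration, FDR control, parameter recovery under a linear
latent signal — not performance on real ADNI/AIBS data.

A note on detectability under these conditions: a causal gene's population
correlation with the planted pattern is w_g/‖w‖ ~ N(0, 1/n_causal), while a
null gene's sample correlation has s.d. ≈ √(1.2/R). At the defaults
(50 causal, 308 regions) the AUROC of any correlation-monotone ranking is
analytically ≈ (2/π)·arctan(0.154/0.062) ≈ 0.76: roughly a third of the
causal genes carry weights too small to be distinguishable from noise at
this region count. Recovery is therefore evaluated primarily by the
precision of the significant lists (empirically ≈ 0.84 at the defaults)
rather than by full-ranking AUROC.

## Numerical and design choices

* RNG: one non-negative integer seed expands into independent named
  substreams (expression, cohort, annotations, CV folds, permutation,
  bootstrap, class permutation, overlap), so the same seed can drive every
  stage without stream collisions; all outputs are pure functions of
  (config, seed).
* CV: folds partition regions via a seeded shuffle; per fold, train-column
  means are re-applied to the held-out block; ties in mean CV error break
  toward fewer components. With an in-span low-noise signal the CV curve
  can keep decreasing for tens of components — selecting a double-digit
  component count is expected behavior of PLS, not overfitting of the
  selector.
* Rank exhaustion during deflation stops component extraction; the public
  fit errors if the requested count is not reached, while CV silently caps
  a fold at its achieved rank.
* Bootstrap SEs use the n−1 sample standard deviation; zero-SE genes
  (degenerate) fall back to the floating-point tiny to avoid division by
  zero.
* Profiles: `test` (n_perm = 1000, n_boot = 200) for development and CI;
  `paper` (10,000 / 1,000) for publication-grade runs. The test suite and
  the acceptance script use the test profile and moderate problem sizes
  (e.g. 1000 replicate 50 × 200 null datasets at n_perm = 199 for
  calibration; twenty 308 × 2000 pipeline runs for global-null FDR
  checks), chosen to make the whole suite run in minutes on one core.

## Known limitations

* No spatial-autocorrelation-preserving (spin) null; both the component
  permutation test and the class profile treat regions as exchangeable.
* Gene-gene correlation structure (co-expression modules) is absent from
  the generator, so FDR behavior under strong gene dependence is untested.
* The two-group contrast is a hard restriction; multi-group designs are
  rejected at validation.
* Under a global null, Benjamini–Hochberg still produces at least one
  rejection with probability ≈ α per dataset (the Simes event); single
  stray significant genes in ≈ 5% of null runs are expected behavior, not
  a defect.
* Enrichment is a plain hypergeometric/permutation over-representation
  test on user-supplied GMT sets; no GO-DAG awareness, PPI networks or
  tissue-specific databases.
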