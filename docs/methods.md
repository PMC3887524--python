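# Methods

## The experimental design being modeled

The pipeline analyzes direct two-color comparisons between two genotypes
that differ only in the parent-of-origin of their sex chromosomes.  Both
RNA samples are hybridized to the same spotted array (one per fluorescent
channel), and replicate arrays swap the dye assignment so that
dye-specific bias cancels in the orientation-corrected average.  The
default contrast is a well-replicated whole-male experiment: eight arrays
(four per dye orientation, split into two batches), ~21,500 exon-specific
spots, one spot per gene.

Per spot, M = log2(ch1/ch2) and A = (log2 ch1 + log2 ch2)/2.  With
orientation o_j = +1 when genotype A is in channel 1, the per-gene
estimand is the mean of o_j·M_gj across arrays — the direct-design linear
model.

## Spot quality control

Three criteria, applied per spot:

1. ≥ 70% of foreground pixels above background median + 2 background SDs,
   in at least one channel (threshold inclusive);
2. median foreground ≥ 3× median background in at least one channel
   (inclusive; an infinite ratio from zero background passes);
3. more than 30 foreground pixels (strict), required of both channels'
   counts.

A spot is retained iff all three hold.  Filtering is idempotent and order
preserving.

## Two-pass loess normalization

**Intensity pass.**  A loess curve of M on A (span 0.3, local linear,
tricube weights) is subtracted.  By default no robustness iterations are
applied.  This is a deliberate choice for direct parent-of-origin
contrasts: a double-digit percentage of spots is genuinely differential
with a common sign, and bisquare reweighting treats those spots as
outliers, pulling the fitted "bias" curve toward the unaffected class and
biasing every fold-change by up to a few hundredths of a log2 unit.  The
plain fit estimates the balanced conditional mean instead.  Robust
fitting remains available through the `iterations` argument for data with
heavy-tailed artifacts.

**Spatial pass.**  A local-regression surface over the slide coordinates
is then subtracted: for each spot, a tricube-weighted plane through its
k = round(span·n) nearest neighbors, with span 0.002 (≈43 spots on a
full-scale array) and a floor of 10 neighbors (widened with a warning).
The spot itself is excluded from its own neighborhood.  With
neighborhoods this small, including the spot would let the surface absorb
10–30% of the spot's own signal; leave-one-out fitting removes the smooth
field while leaving per-spot signal untouched (at 250-spot neighborhoods
the distinction is negligible).  Degenerate neighborhoods are stabilized
by a 1e-10 ridge; translation of the coordinate origin does not change
the result.

No background subtraction is performed before MA computation (background
enters only the QC criteria); a `background_subtract` switch exists.

## Differential expression

For gene g with n_g non-missing arrays: log2FC_g = mean of orientation-
corrected values, s²_g their sample variance, d_g = n_g − 1.  Genes with
n_g < 2 are untestable.  Variances are moderated empirically: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the marginal moments of e give
ψ'(d0/2) = var(e) − mean ψ'(d_g/2) (solved by Newton inversion of the
trigamma function) and s0² from the mean; posterior variances are
(d0·s0² + d_g·s²_g)/(d0 + d_g) and the moderated t has d0 + d_g degrees
of freedom.  When the marginal variance leaves no room for heterogeneity
the prior df is infinite and all variances shrink to the pooled mean —
so equal sample variances are returned unchanged.

Multiple testing: Benjamini–Hochberg q-values, plus an empirical
permutation FDR whose null flips each array's dye orientation over random
sign patterns (identity excluded; default 200 patterns).  The FDR at
threshold τ is the mean null count of |t| ≥ τ over the observed count,
capped at 1 and monotonized q-value-style.  Sign flipping is the natural
exchangeable null for a direct two-color design.  A per-gene median of
the orientation-corrected values serves as the second, model-free
fold-change estimator; the pipeline always reports the Spearman
correlation between the two estimators and between per-batch estimates.

## Tissue specificity

The atlas covers a 20-tissue nonredundant panel.  Preprocessing sets
"absent"-called entries to 1 and, for genes with several probe sets,
keeps the probe set with the largest total signal across tissues.  τ =
Σ(1 − x̂ᵢ)/(N − 1) with x̂ᵢ = xᵢ/max, computed on log2 values so the
absent floor maps to zero and fold-differences among well-expressed
tissues are downweighted (a raw-scale switch exists; only the log
convention's invariance — to powers of the values — is asserted).  A
gene is tissue-specific iff τ > 0.9 strictly and its maximal tissue is
unique.  The quantitative enrichment score of tissue t is log2(value_t)
minus the mean log2 of the other tissues; the score is zero for a
uniform profile.  This log-ratio-to-mean definition is this package's
choice of quantitative enrichment measure.

## Statistical battery

- 2×2 odds ratio ad/(bc) (undefined when b or c is zero) with two-sided
  Fisher exact p (sum of table probabilities ≤ observed).
- χ² goodness-of-fit, uncorrected by default; a Yates-corrected
  2-category variant is provided because corrected and uncorrected
  versions bracket commonly reported values for one-arm-vs-rest tests.
- Chromosomal distribution: counts per arm including unmapped "Other",
  percentages over mapped genes only, per-arm 2-category χ² of the DE set
  against the background proportions, flagged at BH-adjusted 0.05.
- Mann–Whitney group-shift tests (exact for small untied samples, normal
  approximation with tie correction otherwise), reporting group medians.
- Spearman correlation with average ranks for ties.
- Standard major axis regression: slope sign(r)·sd(y)/sd(x) — equal to
  the geometric mean of the two OLS slopes.
- Direction bias: k down of n significant class members, class-vs-rest ×
  up-vs-down Fisher test, and a within-class exact binomial test against
  0.5.

## The synthetic generator

The generator emulates these experimental conditions with planted ground truth:

| parameter | default | meaning |
|---|---|---|
| n_genes | 21,487 | the printed array's spot count |
| n_arrays | 8 | dye orientations alternate +1/−1; two batches of 4 |
| chromosome_proportions | arm spot counts / 16,698 | includes 3.1% unmapped |
| prop_testis_specific | 0.12 | share of genes detected as testis-specific |
| prop_midgut_specific | 0.008 | share detected as adult-midgut-specific |
| testis_median_shift | +0.24 | planted class median, log2 units |
| midgut_median_shift | −0.23 | planted class median |
| background_shift | −0.03 | median of all other genes |
| biological_sd | 0.12 | between-gene spread of true effects |
| technical_sd | 0.07 | per-spot measurement noise (log2) |
| dye_bias_amplitude | 0.30 | cubic-in-A dye bias, max |bias| |
| spatial_amplitude | 0.15 | polynomial + Gaussian-bump slide field |
| qc_fail_fraction | 0.05 | spots constructed to violate one QC criterion |

Class effects are drawn normally around their shift and recentered so
the class median equals the shift exactly.  Channel medians come in
closed form from the planted M and a per-gene baseline intensity
(fg = 2^(A±M/2)); pixel populations are never simulated — the summary
columns the QC criteria reference are drawn directly, and QC-failing
spots explicitly violate one randomly chosen criterion, giving every
spot an exact planted pass/fail flag.  The matching tissue atlas gives
designated specific genes a strong target-tissue signal with rare
low-level leaks elsewhere (τ stays above 0.9 unless ≥8 of 19 off-target
tissues leak, probability ~1e-7) and gives ~10% of genes a second,
weaker probe set to exercise collapsing.

The noise defaults were fixed by design analysis, once, so that the
documented properties of the default dataset hold jointly: the
between-gene effect spread must dominate the estimator standard error
(mean-vs-median Spearman concordance ≥ 0.99 requires spread ≳ 2× the
per-gene SE), while the Monte-Carlo error of the midgut class median
(~170 genes) must stay well inside ±0.03.  All randomness flows from a
single integer seed through independent seed sequences per component;
identical configuration and seed give byte-identical outputs.

**What the generator does not emulate:** print-tip/block structure
(single block, uniform grid), saturation and spot-morphology artifacts,
correlated noise between channels, probe-sequence effects, and
array-to-array intensity scale differences.  Passing recovery tests
therefore demonstrates correctness of the computations under smooth
bias fields and independent log-normal noise, not performance on every
real-array pathology.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default scale (21,487
genes × 8 arrays, ~60 s end to end); unit and null-calibration tests use
900–2,000 genes.  Loess uses exact evaluation (no interpolation delta).
The trigamma inversion is Newton with the standard asymptotic seeds;
failure falls back to infinite prior df with a warning.  Ties in the
largest-remainder rounding of category counts break in the listed
category order.  Fold-change sign convention: positive log2FC means
higher expression in the genotype carried in channel 1 under +1
orientation (the maternal-X/paternal-Y genotype), i.e. downregulation in
the reversed-inheritance genotype.

## Known limitations

- The permutation null flips whole arrays, so with J arrays only 2^J − 1
  distinct patterns exist; at J = 8 the null is adequate but granular,
  and below J = 4 the routine warns.
- The global-flip pattern (all signs reversed) produces |t| identical to
  the observed statistics and is not excluded, slightly inflating the
  null when strong signal is present (conservative).
- Batch effects are modeled only as a label; the pipeline reports
  between-batch concordance but performs no batch correction.
- The τ classifier takes presence calls as given; no re-derivation from
  probe-level data.
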