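# Methods

This note documents the models implemented in `corecruit`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data does and does not emulate.

## The generative model (`corecruit.simulate`)

The generator emulates a normalized two-color ChIP-chip experiment over a
yeast-scale intergenic array.  Defaults: 16 chromosomes, 6,000 regions of
200–1,500 bp (0-based half-open coordinates, non-overlapping per
chromosome).

**Recruiter occupancy.**  Each factor binds each region independently with
probability `bind_rate` (default 0.05 — about the fraction of regions a
well-bound yeast factor occupies, and about the fraction of regions the
co-repressor occupies on a ~6,000-region array, ≈280/6,000).  Log2 ratios
are a two-component Gaussian mixture: unbound ~ N(0, 0.5), bound ~
N(2.0, 0.5).  The companion binding p-value is the upper tail of the
unbound component, so "bound at p < 0.001" corresponds to a log2 ratio
above ≈1.55.  The mixture is a modelling choice: occupancy data of this
kind comes with ratios and p-values but no stated alternative
distribution, and a shifted-Gaussian bound class is the simplest model
with a controllable effect size.

**Co-repressor occupancy.**  y = β₀ + Σᵣ βᵣ·xᵣ + ε, ε ~ N(0, σ).  The
default weights are the nine-recruiter final-model estimates (SUT1 0.454,
NRG1 0.348, ROX1 0.215, SKO1 0.198, CUP9 0.513, YAP6 0.706, CIN5 0.395,
PHD1 0.190, SKN7 0.170; intercept 0.129).  The residual σ defaults to
0.902, calibrated analytically so the generative model's genome-wide R² is
≈0.43: with var(x) = π(1−π)μ² + s² = 0.05·0.95·4 + 0.25 = 0.44 and
Σβ² = 1.395, the explained variance is 0.614, and σ² = 0.614·(1−0.43)/0.43
= 0.814.  The co-repressor's p-values are computed against its own null
component — its distribution at regions where no recruiter is bound,
N(β₀, √(s²·Σβ² + σ²)).

**Missing data** is missing-completely-at-random over recruiter entries at
a default rate of 5% (ratio and p-value masked together).  No missingness
mechanism beyond MCAR is asserted.

**Ground truth** (`SyntheticTruth`) records the weights, intercept, σ, the
recruited set (regions where ≥1 positively weighted recruiter is bound),
the redundancy default, and the derepression slope.  The recruited set is
the synthetic analogue of a high-confidence co-repressor target list (in
a deeply replicated experiment, essentially every truly recruited region
is called); analyses that start from "the target list" use it directly,
while analyses of measurement take the p-value route.

**Deletion strains.**  Deleting recruiter d multiplies its contribution
βd·xd by a redundancy parameter in [0, 1]: 1 reproduces the observed
regime in which single-recruiter deletions leave co-repressor binding
unchanged (other recruiters, or a replacement, compensate); 0 models fully
dependent recruitment.  The Gaussian residual is re-drawn, as a fresh
experiment would be.

**Expression.**  Each gene maps to at most one upstream region
(unidirectional promoters); its log2 expression change in the co-repressor
deletion strain is γ·y(region) + N(0, 1), with γ = 1 by default — deletion
of a repressor derepresses its targets in proportion to how strongly it
sat there.  Unmapped genes receive pure noise.

**Sequences.**  Background bases are i.i.d. from the PWM background; for
each planted (factor, region) pair one site is sampled position-by-position
from the PWM and written at a recorded offset and strand.  Later plantings
can overwrite earlier ones at overlapping offsets; at yeast-like binding
rates and region lengths this is rare and is treated as planting noise.

What the generator does **not** emulate: probe-level intensities, dye bias
and loess normalization (generation starts at normalized log2 ratios);
chromatin or nucleosome context; correlated binding between factors (all
factors bind independently, whereas real recruiters co-occur); spatially
autocorrelated array noise.  Passing tests therefore demonstrate that the
statistics behave correctly under the assumed model, not that the model
captures every property of real arrays.

## Peak calling (`corecruit.peaks`)

Replicates are z-transformed (mean 0, sd 1 per array, cancelling IP
efficiency differences) and combined by the per-element median.  Windows
of 1 kb slide in 250 bp steps; a window's score is the mean standardized
value of the elements it overlaps, and its p-value is the upper tail of
N(μ, σ/√n) for the fitted background.  Numerical conventions:

* **Background fit** assumes one-sided enrichment: μ is the median and σ
  is the root-mean-square deviation of the sub-median half about the
  median (a reflected half-Gaussian fit).  This is robust to upper-tail
  signal: 5% planted positive outliers move σ by well under 5%.
* **Window grid**: candidate starts are multiples of the step that fit
  within the span of the chromosome's elements; a chromosome shorter than
  one window gets a single window anchored at 0.  Windows covering no
  element are skipped, not scored 0 — array gaps must not add null mass.
* **FDR** is Benjamini–Hochberg over all tested windows; windows with
  q < cutoff (strict) are retained.  A permutation FDR was considered and
  rejected: BH is standard, exactly reproducible, and costs nothing.
* **Mock filter** operates element-wise on each peak's representative
  element (its highest-valued element): retained iff signal Z − mock Z > 1
  and mock Z < 2.
* **Collapsing** merges peaks whose windows are within 1 kb on a
  chromosome; the representative of a merged peak is the highest-valued
  representative among its parts, p/q are the best over the merged
  windows.  The operation is idempotent and order-independent.

On null Gaussian profiles the realized window false-positive rate at FDR
0.001 is ~1×10⁻⁴ (tests assert ≤ 3× nominal over 1,000 chromosomes).
Planted 4σ blocks spanning 2.4 kb are recovered with recall ≥ 0.95 and
the representative element always inside the planted span; recall decays
for blocks much narrower than two window widths (≈0.85 at 1.6 kb) because
the BH cut at FDR 0.001 is extremely strict for a mean over few elements.

## Co-occupancy (`corecruit.cooccupancy`)

A target is *co-occupied* iff ≥1 cofactor binds it at p < 0.001, *no-data*
iff all cofactor entries are missing.  Recruiter counts ignore missing
entries (a factor with no measurement at a region cannot contribute to the
count).  Mean co-repressor Z per count bin is reported with its standard
error; single-member bins report SE = 0 with an explicit flag rather than
being dropped, so downstream plots show every bin.  Deletion-strain
comparisons first scale each experiment so its mean over the bound regions
matches the wild-type reference (the scaling is invariant to positive
rescaling of any input) and then use a paired t-test per group; when the
paired differences are identically zero the test reports p = 1.
Derepression uses Welch's unequal-variance t-test ("t-test" without a
stated variant is read as Welch throughout — it is never worse than the
pooled test and costs nothing).  Bound/unbound gene groups are defined at
p < 0.001 and p > 0.05; the ambiguous band between is excluded from both.
Decile binning ranks mapped genes by expression change with stable
tie-breaking and splits them into equal-count bins.

## Recruiter screen (`corecruit.screen`)

Five tests per factor, each converted to an ascending mid-rank percentile
(100·rank/n over the factors with a usable score; an untied best score
gets 100); the composite is the mean percentile over the tests available
for that factor, so a factor missing a PWM or expression data is ranked on
what can be measured.  Ties in the composite break by number of tests used
(more first), then name.

* **(a) Motif over-representation** — a one-sided binomial test: k targets
  with ≥1 PWM hit out of n targets, against the background fraction of
  non-target regions with a hit.  This replaces an external
  over-representation program with a fully specified test of the same
  question.  The background rate is floored at 1/(2·n_background) so an
  empty background cannot yield p = 0.  Enters the composite as −log10 p.
* **(b) Sensitivity** — |TF-bound ∩ targets| / |targets| at p < 0.001.
* **(c) Specificity** — |TF-bound ∩ targets| / |TF-bound|; missing when
  the factor has no targets.
* **(d, e) Top-quartile correlations** — Pearson r over the *union* of the
  two top quartiles (by rank, stable ties), for co-repressor occupancy vs.
  factor occupancy and for downstream derepression vs. factor occupancy.
  The union was chosen over the intersection because an intersection can
  be empty and would silently drop factors; the subset rule is switchable
  (`subset="intersection"`).  Fewer than 8 complete pairs, or zero
  variance in the selected subset, marks the test missing.

**PWM scanning** scores both strands with log2-odds against the background
base distribution.  Significance is exact: scores are discretized to 0.01
log-odds bins and the full null distribution of a background window's
score is computed by dynamic programming, giving the upper-tail p-value of
any observed score.  The threshold (default p < 0.005) is a per-site call
with no cross-position correction.  Windows containing N never hit.  On
short sequences the scanner is tested against brute-force enumeration of
every window with the null obtained by enumerating all 4^L background
words under the same discretization.

In the packaged screen-recovery study (9 planted recruiters, 50 decoys
with the same binding rate, 2,000 regions of 200–500 bp, one informative
8-mer PWM per factor planted at its bound regions), every planted
recruiter with weight ≥ 0.19 ranks in the top 15 of 59 in ≥90% of seeds.
The target list fed to the screen is the ground-truth recruited set, the
stand-in for a deeply replicated high-confidence peak list; defining
targets instead by a single-shot p < 0.001 call on the co-repressor column
yields far fewer targets at the calibrated noise level and starves the
count-based tests (b) and (c).

## Occupancy regression (`corecruit.regression`)

Missing entries are filled with draws from N(column mean, column sd)
computed on the observed entries; ten independent filled matrices are
produced and combined at the *estimate* level (fit each, average the
coefficients), not by averaging the data — the filled values are noise and
averaging them would shrink the filled entries toward the mean and
overstate certainty.  Candidate recruiters are first screened one at a
time (simple OLS; keep iff slope > 0 and p < 0.01): a co-repressor
recruiter must positively predict occupancy on its own.  The multivariate
model is fitted on 5 random half/half splits of the regions; per split the
coefficients are the average over the imputation draws, and the split
model is evaluated on its held-out half (R² clipped to [0, 1]; the
held-out R² never exceeds the training R² by more than 0.05 in tests).
Final parameters are means over splits.  Per-parameter p-values divide the
averaged coefficient by the mean per-fit standard error and refer to a t
distribution with a single fit's residual degrees of freedom — a simple
pooling rule chosen for transparency; it is mildly conservative relative
to combining information across splits, which overlapping half-samples
would not justify anyway.  Recruiters with pooled p > 0.01 are dropped and
the model refitted.  Nested models are compared by a partial F-test on a
full-data fit; the test statistic for the reported ΔR² had to be chosen
here, and the partial F is the standard choice for nested OLS models.
Exactly collinear designs raise an error naming the offending column pair.

At the default study conditions (n = 6,000, calibrated σ, 5% MCAR, three
zero-weight decoys) the full pipeline recovers the exact planted active
set with every weight within ±0.1 in ≥80% of seeds; the residual bias is
the expected ~5% attenuation from imputing MCAR entries with uninformative
draws.

## Study problem sizes

`corecruit.studies` fixes the scales used by the acceptance tests and
script: regression recovery at 6,000 regions (25 seeds in tests, 10 in the
script); screen recovery at 2,000 regions × 59 factors (25 / 5 seeds);
peak calibration over 1,000 / 300 null chromosomes of 100 elements;
count-bin monotonicity at 20,000 regions (to populate the k = 4 bin);
model improvement at 2,000 regions over 20 / 10 seeds.  These sizes keep
each study in the seconds-to-minutes range on one CPU while leaving the
measured rates well away from their thresholds.

## Known limitations

* Factors bind independently in the generator; real recruiters co-occur
  and compete, which is exactly the regime where the univariate screen and
  the regression can disagree (a recruiter whose targets are contained in
  another's loses weight).  The pipeline reproduces that behaviour but the
  synthetic data does not exercise it by default.
* The screen's motif test assumes one planted site per bound region and an
  i.i.d. background; clustered or degenerate motifs are not modelled.
* The mock filter compares representative elements, not window means; with
  element-level mock noise this is the sharper test, but a window-level
  variant would behave differently near the Z = 2 boundary.
* The imputation model is the observed column's own Gaussian; under
  informative missingness it would be biased, and nothing in the package
  detects that.
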