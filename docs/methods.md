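# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, and what the synthetic-data generator does and
does not emulate.

## Scoring model and data representations

A scored cell carries six non-negative integer counts: dicentric
equivalents, centric rings, acentric rings, and compound/terminal/
interstitial fragments (telomere signal at both ends, one end, neither).
Multicentric chromosomes are converted at aggregation time — a chromosome
with C centromeres arises from C−1 pairwise mis-rejoinings and contributes
C−1 dicentric equivalents — while the raw centromere counts remain
representable (`MulticentricEvent`), so no information is lost before
conversion.

Per-cell records are the canonical representation; count distributions
(count → number of cells) and per-class totals are derived views. Published
summary tables often print totals only; such dose points are stored as
totals, and any statistic that needs the per-cell distribution (variance,
dispersion index, U) reports *unavailable* rather than imputing a
distribution. Whichever representations coexist on a dose point are
cross-validated at construction (cell count and class totals must agree).

## Dispersion statistics

For N cells with class total X and per-cell counts k_i:

* yield Y = X/N; sample variance s² = (Σk² − X²/N)/(N−1);
* SE(Y) = sqrt(s²/N) — the empirical form. (Published tables sometimes
  print the Poisson form sqrt(Y/N) at high doses instead; the empirical
  form is used consistently here, and display comparisons are made on the
  Yield/dispersion/U columns, which are formula-stable.)
* dispersion index σ²/ȳ = s²/Y, with SE sqrt(2(1 − 1/X)/(N − 1));
* U = (s²/Y − 1)/SE — the Papworth statistic, asymptotically N(0,1) under
  Poisson scoring.

U and the dispersion index are undefined (reported as `None`) when Y = 0
or X < 2: with X ≤ 1 the SE denominator vanishes. The N−1 variance
denominator is used throughout; on the packaged 0–20 Gy table it
reproduces the printed dispersion and U columns to the two printed
decimals, which the N denominator does not do uniformly.

## LQ calibration

Aberration yields after acute photon exposure follow
Y(D) = c + αD + βD² (one-track term αD, two-track term βD²; c is the
background yield). Per-dose totals (D_i, X_i, N_i) are sufficient
statistics under Poisson scoring, so the fit consumes totals:

maximize  l(θ) = Σ_i [X_i ln(N_i λ_i) − N_i λ_i],  λ_i = c + αD_i + βD_i².

Numerical choices:

* bounded quasi-Newton (L-BFGS-B) with the analytic gradient and bounds
  θ ≥ 0; this is standard, well-tested constrained-GLM practice and avoids
  a hand-rolled projected-Newton loop. Convergence: relative likelihood
  change below 1e-14 or projected gradient below 1e-8, max 200 iterations.
* starting values from unweighted least squares on the observed yields,
  clipped into the feasible region;
* SEs and covariance from the inverse observed information
  H = Σ X_i λ_i⁻² v_i v_iᵀ (v = (1, D, D²)); when an estimate sits on the
  zero boundary it is listed in `metadata["boundary"]` and its SE should
  not be trusted;
* `fix_c_zero` / `fix_alpha_zero` drop columns from the design (pure-
  quadratic fits, e.g. for rings, and the closed-form check
  β̂ = X/(N·D²) for a single dose with both other terms fixed);
* goodness of fit is the Poisson deviance with df = n_doses − n_free; the
  saturated case (df ≤ 0) reports an undefined p-value.

The packaged CABAS coefficient files (0, 0.021, 0.387 for dicentrics;
0, 0.001, 0.051 for rings) are external reference fixtures: the regression
protocol behind them is unstated and they are inconsistent with an LQ fit
over the full 0–20 Gy distributions (they would predict ~155 dicentrics
per cell at 20 Gy against ~13.8 observed). Nothing in this package fits
toward them; the fitting code is validated by parameter recovery on
simulated data instead. Likewise no attempt is made to reproduce published
"R² for linearity" values, whose regression variables are unspecified.

## Dose estimation

The point estimate inverts the calibration curve at y = X/N: D = 0 for
y ≤ c, otherwise the positive root (−α + sqrt(α² + 4β(y − c)))/(2β)
(or (y − c)/α for β = 0). The 95% interval takes the exact (Garwood)
Poisson limits on the raw count,

lower = χ²(α/2; 2X)/2 (0 when X = 0),  upper = χ²(1 − α/2; 2X + 2)/2,

divides by N and inverts through the same curve. This *counts-first* CI
construction reproduces published triage intervals exactly (e.g. X = 22,
N = 50 → 1.27–2.20 Gy), which a delta-method interval on the yield does
not; the delta method remains available as an explicitly labelled
alternative (`method="delta"`). Calibration-curve uncertainty is *not*
folded into the interval — the interval is conditional on the curve, so
its nominal 95% coverage holds when the curve is treated as known (the
coverage test asserts ≥ 90% over Poisson replicates at 2 Gy). Estimates
from X = 0 report 0 (0–UCL) rather than failing.

Triage truncation returns the shortest scored-cell prefix reaching either
50 cells or 30 cumulative dicentric equivalents, the abbreviated scoring
convention for mass-casualty triage.

## Spectrum comparison

Category counts per (dose × donor × preparation) cell of the design are
modelled as multinomial with baseline-category logits: for non-reference
category k,

η_k = a_k + d_k·donor + b_k·D² + g_k·D²·G2,

G2 = 1 for G2-PCC preparations, 0 for metaphases. Dose enters as D² only:
with few dose levels the linear LQ term is poorly identified and is
deliberately omitted. The interaction g_k is the quantity of interest —
whether a category's share responds to dose differently between
preparations. Choices the published analysis leaves open, fixed here:

* reference category: compound fragments (the largest class), so every
  coefficient reads as "relative to compound fragments";
* aggregated counts (not per-cell multinomials), since per-cell category
  co-occurrence is not available in summary tables;
* covariance from the inverse observed information at the optimum; Wald z
  per coefficient.

Because the exact published model variant and covariance estimator are
unknown, no numerical equivalence with published p-values is claimed —
only qualitative agreement (on the packaged data the dicentric interaction
is negative, matching the published direction). The fit itself is
Newton-Raphson with step halving on the exact multinomial log-likelihood
(analytic gradient and information matrix) and is cross-checked in the
test suite against an independent multinomial-logit implementation on
expanded data. Fitted probabilities are invariant to the reference choice;
empty categories are dropped with a warning; non-convergence (e.g.
separation) raises with diagnostics.

Pearson correlation of per-dose yield series uses the standard
product-moment form and reports NaN for zero-variance input.

## Synthetic data generator

`simulate_score_sheet` draws per-cell counts around an LQ mean per class,
one independent stream per aberration class — published tables give no
co-occurrence information, so independence across classes is the explicit
simplifying assumption. Dispersion models:

* `poisson` — the whole-body photon reference case (Var/Mean = 1);
* `neg_binomial(shape)` — gamma-mixed Poisson, Var = λ + λ²/shape;
* `partial_body(fraction, background)` — each cell is irradiated with
  probability f (mean λ(D)) or unexposed (mean background); a
  two-component mixture with no cell-death weighting, which goes beyond
  what the underlying study analysed and is labelled accordingly.

Alternatively a single total-yield curve plus fixed spectrum proportions
draws a per-cell total and splits it multinomially across the six classes.
All randomness flows from one mandatory seed through numpy's PCG64
generator (recorded in the sheet's sample id); identical config and seed
give byte-identical CSV output. `simulate_study` builds multi-arm designs
(donor × preparation) on a shared dose grid, null-by-construction when
arms share parameters.

What passing simulation tests show — and do not show: they validate the
estimators under their own assumptions (independent Poisson-family counts,
correct LQ mean). Real scoring data add inter-scorer variation, culture-
time selection effects, class co-occurrence within cells and donor
heterogeneity, none of which the generator emulates; agreement with the
packaged real tables is therefore tested separately and directly.

## Problem sizes used in the test suite

Simulation-backed properties run at desk scale chosen to keep Monte-Carlo
error well below the asserted margins: U-statistic calibration at 500
replicates of 100 cells; LQ parameter recovery at 100 replicates of six
doses × 2000 cells; CI coverage at 1000 replicates; spectrum type-I error
at 500 replicates of 8 design cells × 400 aberrations; study-level null
uniformity and power at 200 replicates each. The full suite runs in well
under a minute on one CPU.

## Known limitations

* No partial-body *estimation* (Dolphin/contaminated-Poisson); the
  simulator can generate such data but the estimator assumes whole-body
  exposure.
* Exact-Poisson intervals ignore calibration-curve uncertainty by design;
  for curves fitted on small calibration sets the reported intervals are
  anti-conservative.
* The multinomial model treats design cells as independent multinomial
  draws; overdispersion between cells (donor effects beyond the intercept
  shift) would inflate Wald significance.
* The "±SE" sometimes printed alongside published dose estimates is not
  reproduced by yield-SE/slope propagation and is not a package output;
  confidence limits are the primary uncertainty statement.
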