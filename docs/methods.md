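# Methods

`strawsugar` implements a mid-infrared chemometric calibration workflow for
predicting enzymatic sugar release from untreated wheat straw, together with
a synthetic data generator that reproduces the statistical structure such a
calibration rests on. This note documents the models, the numerical choices
and the limits of what the synthetic experiments can show.

## The calibration model

The response is sugar release y (glucose, xylose or their total, in g per g
dry matter, measured by a high-throughput pretreatment/enzymatic-hydrolysis
assay). The predictors are photoacoustic mid-IR absorbances on the
4000–600 cm⁻¹ grid at 4 cm⁻¹ (851 points). Because neighbouring wavenumbers
are almost collinear, the regression is PLS1 by NIPALS: with centred design
X and response y, each factor extracts

    w = X'y / ‖X'y‖,   t = X w,   p = X't / t't,   q = y't / t't,

followed by deflation `X ← X − t p'`, `y ← y − q t`. After F factors the
absorbance-space coefficients are `b = W (P'W)⁻¹ q`, and predictions are
`ŷ = ȳ + (x − x̄)·b`. PLS1 (one response at a time) rather than PLS2 is used
because the three responses need different factor counts. NIPALS is the
production algorithm; an SVD-based implementation and OLS-at-full-rank serve
as independent cross-checks in the test suite only.

Factor choice: leave-one-segment-out cross-validation over seeded random,
equal, contiguous segments (default 10), followed by a parsimony rule — the
smallest F whose RMSECV is within 2% of the minimum. The default factor cap
in the workflow driver is 15 (the cross-validation operation itself defaults
to 20); fitted models on realistic data use 1–5 factors.

Variable selection is Martens' uncertainty test: with M cross-validation
segments, the jackknife variance of coefficient j is

    s_j² = (M−1)/M · Σ_k (b_j⁽ᵏ⁾ − b_j)²,

and wavenumber j is kept when |b_j|/s_j exceeds the two-sided t critical
value at α = 0.05 with M−1 degrees of freedom (zero-variance nonzero
coefficients are kept). The model is refit once on the kept variables at the
same factor count; iterating the test to convergence is possible but not
default.

## Outlier screening

Calibration samples are screened on the influence plot of a preliminary
fitted model: Hotelling T² over the F score dimensions (training score
variances, n−1 denominator; the F-distribution limit
`T²crit = F(n−1)/(n−F)·F_q(F, n−F)` at the 0.975 quantile) against the
Q residual (squared off-plane distance; empirical 0.975 training quantile —
distribution-free, avoiding moment-based approximations at moderate n).
A sample is removed when either statistic exceeds its limit; an explicit
exclusion list can emulate manually curated outlier sets. One caveat is
structural: when the screened set is also the threshold source, the
empirical Q quantile can flag at most about 2.5% of it, so heavy
contamination partially masks itself; `flag_outliers` therefore accepts a
`reference` report when thresholds should come from a trusted population.
The Hotelling limit's nominal false-flag rate assumes approximately normal
scores; on skewed data the realised rate runs slightly above nominal.

## Figures of merit

R² = 1 − SSE/SST and RMSE = √(Σ(fᵢ−yᵢ)²/n), computed for the
cross-validated predictions and for the untouched external-validation set
(stratified 2/3–1/3 split by variety and site, largest-remainder rounding;
the model is frozen before external evaluation). The precision floor of the
reference assay is

    SDL = √( Σⱼ Σᵢ (y_ij − ȳ_j)² / (m·n − 1) )

from m assay replicates of n samples, and RMSE_EV/SDL near 1 marks a
calibration limited only by reference precision. The m·n−1 denominator is
the convention this family of calibration studies reports and is the
default; note it underestimates the replicate standard deviation by the
factor √(n(m−1)/(mn−1)) ≈ 0.816 at m = 3, so the unbiased pooled
denominator n(m−1) is available via `sdl(..., denominator="pooled")` and is
what the estimator-consistency checks use.

## Subset decorrelation

Measured glucose and xylose correlate strongly (r ≈ 0.8), so a model for one
sugar can lean on regions belonging to the other. The workflow partitions
the calibration set into k = 3 equal subsets minimising the worst
within-subset |r(glucose, xylose)|, refits per-subset models and compares
their coefficients. The partition search is deliberately constructive:
random-start pair-swap local search reliably stalls well above the optimum,
so subsets start from equal bands along the correlated direction
u = z_g + z_x (which moves covariance into between-subset mean differences)
refined by an exchange of the outer bands' smallest-|v| members
(v = z_g − z_x; on-diagonal points carry positive covariance) against the
middle band's largest-|v| members, the exchange fraction swept over 0–0.2.
A best-improvement pair-swap polish then runs with a monotone objective
(max |r| first, total squared correlation as tie-break). For an exactly
bivariate-normal population with r = 0.8 this family attains the population
optimum, max-subset |r| ≈ 0.385; individual n = 600 draws fluctuate around
it, so worst-case guarantees below ~0.45 are not achievable for every draw —
a bound documented honestly in the test suite. Plain random partition is
kept as a baseline (`method="random"`).

Interpretation support: contiguous grid runs where |b| exceeds its 0.9
quantile are merged into regions, each labelled with its sign and the
nearest entry of the packaged 16-band mid-IR assignment table within
30 cm⁻¹ (the tolerance bridges the band shifts reported between crystalline
and amorphous cellulose).

## The synthetic data generator

Because no public spectra/response dataset exists for this assay, the
generator emulates the study conditions end to end; it is first-class,
tested code.

* **Spectra.** Five components — amorphous cellulose (bands at 898, 2920,
  2850 cm⁻¹), crystalline cellulose (1053, 1111, 1160, 1429), xylan (1735,
  1240, 1460), lignin (1510, 1600, 1429) and water/carboxylates (3380,
  1650) — each a sum of Gaussian peaks (FWHM parameterisation; Gaussian
  rather than Voigt because a linear calibration only needs band overlap
  structure). A sample's spectrum is a concentration-weighted sum plus a
  gentle sloping baseline over a positive photoacoustic background and white
  instrument noise (σ_spec = 0.01 absorbance).
* **Concentrations.** Mean-one lognormals. A shared "plant maturity" latent
  factor loads positively on amorphous cellulose and xylan (0.36) and
  negatively on lignin (−0.25), inducing the glucose–xylose correlation the
  decorrelation analysis needs.
* **Responses.** Linear in concentrations with signs encoding the accepted
  biochemistry: amorphous cellulose drives glucose (+0.060), xylan drives
  xylose (+0.050), lignin inhibits both (−0.033, −0.023) and crystallinity
  retards glucose (−0.027); intercepts 0.23 and 0.19 g/g. Total is the exact
  sum. Residuals not predictable from the spectra are drawn correlated
  between the sugars (ρ_y = 0.6, σ_y = 0.022/0.017): independent residuals
  cannot reproduce a measured r ≈ 0.82 at external-validation R² ≈ 0.65–0.7,
  because noise attenuation would cap the measured correlation near 0.65
  even with perfectly correlated latents — the shared part of the residual
  is biology, not assay error.
* **Replicates.** m = 3 assay replicates per sample with correlated
  glucose/xylose assay noise (σ = 0.016/0.010, ρ_rep = 0.6875) and totals as
  exact sums, so the implied total-sugar replicate scatter is 0.024 g/g.
* **Defaults as study conditions.** n = 1068 samples over 9 sites and 20
  varieties; total sugar mean ≈ 0.42 g/g with range covering 0.30–0.57;
  measured glucose–xylose r ≈ 0.82–0.85; the full workflow lands at external
  R² ≈ 0.65–0.72 with 1–2 factors. These constants were calibrated once
  against those targets and then frozen.

**What the synthetic experiments do not show.** Spectra are exactly linear
in component concentrations with additive Gaussian noise — no photoacoustic
saturation, thermal-diffusion depth effects, moisture bands, or scan-level
noise; metadata (site, variety, year) carries no systematic response effect,
so site-level confounding and cluster structure in the sugar scatter are not
emulated. Passing tests therefore demonstrate correctness of the estimators
and the workflow under a well-specified linear world, not instrument-level
robustness.

## Numerical and degenerate-input conventions

Grids are stored strictly descending (4000 → 600 cm⁻¹); ascending input is
re-ordered on read, and derivatives are taken on the ascending physical axis
so their sign is interpretable. Savitzky–Golay edges use polynomial
extension (the boundary window's polynomial evaluated off-centre), keeping
the 851-point grid length. "Normalisation by the mean" is division by the
per-spectrum mean (a scatter correction), not mean-centring; SNV uses the
n−1 standard deviation. Missing values are input errors, never imputed.
NIPALS stops early if the covariance norm underflows (rank exhaustion);
zero-variance responses, constant spectra for SNV, zero-mean spectra for
mean normalisation, extrapolating regrids, even smoothing windows and
all-variables-rejected selections raise immediately with instructive
messages. All randomness flows through explicit integer seeds; identical
seeds give bit-identical datasets, splits and cross-validation segments.

## Problem sizes

Default experiments run at the study scale (n = 1068 spectra × 851 points);
statistical acceptance checks use 20 seeded replicates of the full workflow,
20 replicates of a 200 × 250 variable-selection problem, and n = 600
decorrelation cohorts. The complete suite plus the acceptance script run in
a few minutes on one CPU.
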