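# Methods

## The kernel-set model

Maize yield responds to stress around flowering mainly through kernel
number per plant (KNP). The causal chain modelled here is

    plant growth rate (PGR) → ear biomass at 15 d after anthesis (EB) → KNP

with both links described by threshold hyperbolae: no ear growth below a
base growth rate `PGR_b`, no kernel set below a base ear biomass `EB_b`,
and saturating returns above each threshold governed by an initial slope
(`IS_EB`, `IS_KN`) and a curvature (`C_EB`, `C_KN`). The asymptotic
plateaus are `IS/C`; zero curvature degenerates to a line and the plateau
is reported as infinite. The curves are continuous at the thresholds and
monotone non-decreasing; both properties are enforced by construction and
checked by property tests.

The six coefficients are genotypic: one set per hybrid is assumed to
apply to every plant, which is the standard working assumption for this
family of models. Published values for four commercial hybrids (H1–H4)
are shipped in `REFERENCE_HYBRIDS` and used as generating truth
throughout the test suite.

### Fitting

`fit_kernelset` estimates the coefficients in two sequential stages —
EB-vs-PGR first, then KNP-vs-EB — mirroring how the two relationships
are presented and fitted in practice, rather than as one joint
likelihood. Each stage is bound-constrained least squares
(`scipy.optimize.least_squares`) on the raw piecewise form; the hinge
`max(0, x − b)` is kept non-smooth deliberately (finite-difference
gradients handle it) so the fitted object is exactly the model reported.
Bounds are the coefficient invariants: thresholds ≥ 0 and at most the
largest observed predictor, slopes > 0, curvatures ≥ 0.

Initialization: threshold ← 0.9 × smallest predictor with a positive
response; slope ← secant slope of the lowest-predictor third; curvature ←
slope / plateau, with the plateau guessed from the top decile of the
response. Five lognormally jittered restarts (fixed internal seed 1234)
plus a zero-threshold start guard against local minima; the lowest
residual sum of squares wins. On instances of a dozen points the winner
matches or beats a dense brute-force lattice search. Loss is unweighted
least squares; no weighting is applied because none is stated for the
reference fits.

Identifiability caveats: when the data do not span a threshold (e.g.
`PGR_b` = 0.13 but all plants grow faster than 0.5 g plant⁻¹ d⁻¹) the
threshold is inferred from curvature alone and is the least precise
coefficient; with noise-free data it is still recovered exactly, but
under observation noise its per-fit scatter is large even though the
median across replicate fits stays close to truth. Datasets with fewer
than 8 points, or with all-zero ear biomass, are rejected as
non-identifiable.

## Allometric biomass estimation

Tagged plants are phenotyped non-destructively. Calibration regressions
fitted on destructively sampled border plants (OLS via statsmodels):
shoot biomass ~ stem volume before flowering; shoot biomass ~ stem
volume + maximum ear diameter after flowering (main effects only — no
interaction term is assumed); ear biomass ~ ear diameter². Stem volume
uses a cylinder, π(d/2)²h; no volume formula is canonical, so the
cylinder — the convention in the allometric calibration literature — is
isolated in `stem_volume` and swappable. One model is fitted per hybrid
per stage. Negative biomass predictions are floored at zero with a
logged warning rather than propagated.

## Growth and thermal time

Thermal time is Σ max(0, T − 8 °C) over daily means; sub-base days
contribute zero (the standard growing-degree-day clamp). PGR over the
30-day flowering interval is reported per calendar day
(g plant⁻¹ d⁻¹) — the basis used in trait tables — with a per-°C d basis
(mg plant⁻¹ °Cd⁻¹) retained because the measurement protocol defines the
rate against accumulated thermal time; the two are related by the factor
thermal time / calendar days and round-trip exactly. Negative growth is
kept (with a warning), not clipped: the EB = 0 branch of the model
absorbs shrinking plants. Plant-to-plant variability is
CV_PGR = 100 × sample SD / mean.

## Trait definitions and conventions

* Kernel weight: 400-kernel sample mass, converted to dry matter and
  reported as dry / (1 − 0.145), i.e. at 145 g kg⁻¹ moisture. The
  conversion direction (field moisture measured upstream, then
  standardized) is a package convention; only the reporting basis is
  externally fixed.
* KNP from yield: (yield in g m⁻²) / kernel weight (g) / density.
* Relative yield: strictly paired to the unshaded control of the same
  environment × hybrid × block; computed as `100 * (y_t / y_c)` so a
  control divided by itself is exactly 100 in floating point. Marginal
  relative yields are means of per-plot ratios, not ratios of means.
* Barrenness: share of plants with fewer than 10 kernels; exactly 10 is
  not barren.
* Partitioning efficiency EB / total biomass; seed-set efficiency
  KNP / EB. Note the tabulated seed-set efficiency of a treatment is a
  mean of per-plot ratios, which differs from the ratio of treatment
  means.
* Optimum stand density is the argmax over the tested discrete levels —
  no curve is interpolated, because only tested densities are reported —
  and the supra-optimal decline is the % yield drop from the optimum to
  the highest tested density.

## Trial statistics

Fixed-effects RCBD ANOVA through statsmodels OLS: environment, hybrid
and treatment crossed, blocks nested within environment
(`C(env):C(block)`), blocks fixed (no mixed model is implied by the
design). Type II sums of squares handle the unbalanced shading layout —
the earliest window is tested in one environment only — without
order-dependence, matching the marginal-means philosophy; the unbalanced
layout is kept rather than dropping the extra window. Marginal means are
least-squares means: equal-weight averages of model predictions over the
reference grid of the other factors, with standard errors from the
coefficient covariance; unobserved grid cells trigger an estimability
warning since their predictions lean on the additive structure. Tukey
comparisons use the studentized range (scipy), Tukey–Kramer standard
errors for unequal replication, and report the scalar honest significant
difference q(α, k, df)·√(MSE/n) alongside, as trial tables print it.
Under a null simulation with no hybrid effect, the hybrid F-test holds
its nominal 5% size (measured 0.050 over 500 simulated trials in the
acceptance suite).

## The synthetic-trial generator

The generator reproduces the *structure* of the field studies, not their
field values:

* Shading trials: two sowing-date environments, four hybrids, five 7-day
  windows (−21…−14, −14…−7, −7…0, 0…+7, +7…+14 d relative to anthesis)
  plus an unshaded control, three blocks, 15 tagged plants per plot at
  8 plants m⁻²; the earliest window only in the first environment.
  Density trials: three environments, densities 5/7/9/11 plants m⁻²,
  three blocks.
* Each plant draws a lognormal potential PGR (CV 30% by default, the
  middle of the reported 24–36% range) around a hybrid mean taken from
  the reported control-period growth rates (3.93, 3.78, 2.88,
  3.48 g plant⁻¹ d⁻¹ for H1–H4). Environments scale means down by 6%
  per later sowing; blocks carry a 3% CV multiplicative effect. Every
  plot's plants are drawn independently, as in a real trial where the
  control is a physically distinct plot — this is what makes the RCBD
  residual an honest error term (and the F-test calibrated).
* Shading multiplies instantaneous growth during the window's overlap
  with the ±15 d measurement interval by 1 − (1 − τ)·s·w, with τ = 0.2
  the cloth transmission (80% PAR reduction), s ∈ [0, 1] the genotype's
  shading sensitivity and w a triangular proximity weight (1.0 for the
  window ending at anthesis, 0.6 adjacent, 0.2 outermost), chosen so the
  anthesis-ending window is the most damaging. Interval-mean PGR is
  therefore scaled by 1 − (overlap/30)·(1 − τ)·s·w. Because only this
  average-growth pathway is modelled, simulated relative-yield losses
  are milder than field values; all downstream checks are of orderings
  and correlations, not magnitudes. Default sensitivities (0.2, 0.9,
  0.7, 0.1 for H1–H4) encode the observed pattern that H2 and H3 are
  the susceptible hybrids.
* Crowding scales mean PGR by (d/5)^(−γ(2 − tolerance)) with γ = 0.5 and
  tolerance = 1 − sensitivity, anchoring hybrid means at the lowest
  tested density; one latent sensitivity thus drives both shading loss
  and crowding intolerance, which is precisely the hypothesis structure
  the response-summary correlation is meant to detect.
* EB is the genotype hyperbola evaluated at realised PGR times
  multiplicative Gaussian noise (CV 10% by default), truncated at zero;
  KNP is the second hyperbola evaluated at the *realised* EB times its
  own noise, so each curve holds between observed quantities and with
  all noise off every plant lies exactly on the generating curves. KNP
  is kept continuous (expected kernels) rather than rounded, preserving
  that closure.
* Morphometrics are generated backwards from the allometric generating
  truth (shoot biomass = 20 + 15·PGR_potential g; stem volume from the
  preflowering line with intercept 5 g and slope 0.12 g cm⁻³; ear
  diameter from EB = 1.6 d²) with measurement noise at 20% of the
  observation CV per dimension — a share set so that the preflowering
  calibration r² on default-noise data sits in the high-0.7s to 0.9
  range reported for such calibrations. Kernel weight is constant per
  hybrid (reported per-hybrid means) with noise at 30% of the
  observation CV; kernel-weight plasticity is deliberately not
  modelled, as the mechanistic model covers kernel number only.
* Plot yield is density × mean KNP × kernel weight on a 1 m² basis,
  expressed in Mg ha⁻¹ at standard moisture; `knp_from_yield` inverts
  this construction exactly. Anthesis is a single plot-level date;
  plants within a plot are exchangeable (no spatial arrangement is
  modelled). Daily temperatures are a sinusoid around 24 °C with 1.5 °C
  noise — enough to exercise thermal-time code, not a weather model.

What passing tests on this generator do **not** show: that field
relative-yield magnitudes, kernel-weight responses, or any Table-level
field means are reproduced — raw field data are not publicly deposited,
so the statistical layer is validated on calibration (size, power,
exactness) and the model layer on parameter recovery against the
published coefficients.

## Problem sizes and numerical choices

Recovery benchmarks use 60 plants per fit and 20 replicate datasets per
hybrid — matching the per-replicate tagged-plant scale of the field
design — with medians reported to damp the heavy-tailed per-fit scatter
of threshold coefficients. The null-calibration study uses 500 simulated
trials; the correlation-structure study 50 paired trials. Optimizer
tolerances are 1e-14 (xtol/ftol/gtol); OLS fits are exact to the normal
equations at 1e-10; balanced ANOVA decompositions conserve total SS to
1e-8; studentized-range quantiles agree with published tables to three
decimals.

## Known limitations

* No joint hierarchical (mixed-effects) fit across replicates; replicate
  coefficient spread is summarised by a one-way ANOVA instead of a
  random-effects variance.
* No standard errors or confidence intervals on individual coefficients
  beyond that replicate-level analysis.
* Kernel weight is static per genotype; grain-filling plasticity is out
  of scope.
* The stress model acts only through interval-mean growth; carry-over
  effects outside the measured window, leaf-area dynamics and radiation
  interception are not modelled.
* Optimum density is the best tested level, not an agronomic or economic
  optimum from a fitted yield–density curve.
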