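# Methods

## The model

A cold-treatment bioassay exposes boxes of artificially infested fruit to a
target temperature for `t` days and counts the insects that survive to
pupation.  Writing `n_i` for the expected number of insects in box `i` had
it not been treated (the "estimated number treated") and `k_i` for the
number that died (`n_i` minus pupae recovered, both rounded to integers and
the difference clipped at zero), the model is

* mean: `g(π_s(t)) = α_s + β_s t` with `g` the probit or logit link and `s`
  the life stage (egg, L1, L2, L3).  Controls (`t = 0`) are ordinary data
  points; no control-mortality correction is applied, because natural
  egg-to-pupa failure is part of what the control mean already absorbs.
* observation: `k_i ~ BetaBinomial(n_i, π, ρ)` parameterized by mean `π`
  and intraclass correlation `ρ ∈ [0, 1)`; `ρ → 0` recovers the binomial.
  Between-box heterogeneity (egg load, fruit condition) makes counts
  overdispersed, and an unmodelled `ρ` produces badly overconfident
  intervals.
* dispersion submodel: `ρ_s(t) = logistic(d_s + e t)` — per-stage
  intercepts with a single shared time slope by default.  A stage-specific
  slope (`disp_slope="per_stage"`) and a constant (`"none"`) are available;
  the shared slope is the minimal structure that lets dispersion change
  along the duration axis.
* random effects (optional): Gaussian intercepts for replicate or
  replicate×cultivar on the link scale, integrated out group-by-group by a
  Laplace approximation.  A 9-point adaptive Gauss–Hermite rule replaces
  Laplace for any group whose curvature at the conditional mode is
  ill-conditioned (below 1e-6), with the proposal spread capped at three
  prior standard deviations.

Maximum likelihood throughout.  Fitting is deterministic: an L-BFGS-B start
from empirical link-scale regressions on adjusted proportions
`(dead + 0.5)/(n + 1)`, a Nelder–Mead polish (restarted once), and a
convergence flag from coarse central-difference gradients (step 1e-3,
relative tolerance 1e-3; the coarse step matters because the likelihood
carries ~1e-7-level branch noise near `ρ → 0`).  The covariance is the
inverse of a numerical observed-information matrix; if that matrix is
singular the pseudo-inverse is used and the fit carries a warning.  The
marginal (random-intercept) likelihood is optimized from two starts —
σ = 0.3 and the σ→0 boundary, where the marginal equals the fixed-effects
likelihood — because the profile in log σ can be flat enough near the
boundary to stall a single run.  Fits to a reference dataset agree with
glmmTMB (betabinomial family, matching dispersion formula and random
intercepts) to four decimals in coefficients, σ̂ and log-likelihood.

Complete separation (a stage with no partially-killed box) is flagged on
the fit, never silently estimated; a stage observed at fewer than two
distinct durations is an error.

The beta-binomial log-pmf is evaluated through `betaln`/`gammaln` for
speed; below `ρ = 1e-8` it switches to the binomial branch, where the
beta-function form loses more precision than the model difference is
worth.  Mean probabilities are clipped to `[1e-12, 1 − 1e-12]`.

## Lethal times and Fieller intervals

`LT_p = (g(p) − α_s)/β_s`.  Probit 9 is the constant `0.999968`, stored at
full precision.  The Fieller interval solves
`(a − Lb)² = z² (V_a − 2L C_ab + L² V_b)` for `L`, with `a = g(p) − α̂`,
`b = β̂` and the 2×2 fixed-effects covariance block; `z` is the standard
normal quantile.  When `g = z² V_b / b² ≥ 1` the confidence set is the
complement of a finite interval or the whole line, and the result says so
explicitly (`case = "exclusive"`/`"unbounded"`).  For mixed fits the
default covariance is the fixed-effects block of the marginal information
(whether the original analyses conditioned on the random effects or used
the marginal covariance is not documented anywhere; both amount to the
same block here because σ enters only through the marginal likelihood).

## Efficacy arithmetic

Treated-number extrapolation scales a control interval by
`n_treated_fruit / n_control_fruit`:

* `two_sided_t` (default): `(μ ± t_{0.975, r−1} · s/√r) · scale`;
* `one_sided_t_wearing`: lower limit of the one-sided 95% t interval on the
  standard error;
* `ippc_sd`: one-sided 95% normal limit with the standard deviation in
  place of the standard error — an approximation to the IPPC convention,
  labelled as such.

On the published control counts (10,226; 10,598; 10,625 per 200 fruit) all
three reproduce their printed counterparts: 506,383 / 515,461 / 515,926
(±2, from rounding in the printed inputs).

The confidence that true mortality ≥ m after s survivors among n treated
is the binomial tail `C = 1 − Σ_{i≤s} C(n,i)(1−m)^i m^{n−i}`, evaluated in
log space (`−expm1(n ln m)` for s = 0) so it is exact at n in the millions.
`required_n` inverts the zero-survivor case and pins the boundary down by
direct evaluation; the minimum n for 95% confidence at probit 9 is 93,616.
The efficacy report conservatively takes the *minimum* across the
available treated-number estimates before computing the confidence.

## Mortality bookkeeping and temperature QA

Expected totals for treated boxes are matching-group (cultivar × replicate
× stage) control means; mortality `1 − pupae/expected` is clipped to
[0, 1] because a lucky box can out-yield the control mean.  Summaries
report box-level medians and ranges (boxes, not fruit, are the
experimental unit).

Cool-down time is the elapsed time until fruit-core probes first read
below 3.5 °C — by default the large-scale "majority" rule (strictly more
than half the probes), with the per-probe-mean rule of the tolerance years
as an alternative; resolution is one sampling interval and a
never-reached threshold is a flagged result, not an exception.  Constancy
is the percentage of post-cool-down fruit readings within ±0.5 °C of 3 °C,
inclusive at both band edges.  Calibration offsets are ice-bath negated
means, so any constant probe bias is absorbed exactly.

## Synthetic data: what it does and does not emulate

The generators reproduce the study *designs* — 2018: 4 stages × 2
cultivars × durations {0,5,6,7,8,10} d × 4 replicates × 3 boxes of 5
fruit; 2019: third instars, durations {0,8,10,11,13,14,16,18} d, 4
replicates × 5 boxes of 10 fruit (810 infested fruit per replicate
counting the 10 dissection fruit); large-scale: 3 replicates of 3,400
fruit at 18 d, 180 at 8 and 10 d, 200 controls, 10 dissections.

Default truth: logit link with (α_s, β_s) back-solved from the published
'Hayward' LT_50/LT_99.9968 pairs (egg −3.195/0.830, L1 −3.086/1.348,
L2 −3.289/0.988, L3 −3.161/0.780 — so true L3 LT_99.9968 ≈ 17.3 d); a
+0.5 link-scale susceptibility shift for 'Zesy002'; eggs per fruit from a
rounded truncated normal (mean 90, sd 20 — the sd is a synthetic choice
consistent with the printed CI of the infestation mean at a sample of a
few dozen fruit); egg-to-pupa control rates 0.50 ('Hayward') and 0.17
('Zesy002'), matching the relative pupal yields of the two cultivars;
ρ = 0.05 constant and replicate-intercept sd 0.25, both synthetic choices
sized so that overdispersion is real and detectable (no between-box
variance estimates were ever published).  The large-scale generator uses
51 pupae/fruit (sd 5.4) and treats the 18-day survival probability as 0 —
the trial's observed outcome under mortality beyond the probit-9 level —
while 8- and 10-day lots survive at the model rate.

What passing tests on these data do **not** show: that real box-level data
follow a beta-binomial with logistic-in-time dispersion, that replicate
effects are Gaussian, or that egg loads are normal.  The generators are a
correctness harness with known truth, not a biological simulation of
larval development.

## Scaled-down refits of the published totals

Only duration-level totals (pupae retrieved P and estimated treated E per
cultivar × stage × duration) were published; the original fits used
box-level data with replicate/replicate×cultivar random effects.  Refits
of the aggregated totals are therefore *near* but not *on* the published
lethal times: the third-instar LT_99.9968 from the pooled totals is
15.6 d (AIC-chosen logit, combined cultivars) and 15.3 d ('Hayward',
logit) against published box-level values of 17.3 and 17.31 d.  The gap is
a property of the data granularity, not of the estimator: glmmTMB fit to
the same totals gives identical numbers, and plausible alternative
structures (constant dispersion, probit link, equal per-box
disaggregation) span 13.9–19.5 d around the published values.  The
package reports what the available data support and documents the
difference rather than imitating the unpublishable fit.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to be statistically
informative on one CPU: Fieller coverage over 300 datasets at the 2019
design scale (single cultivar), probit-9 LT recovery over 100 seeds at the
same scale, dispersion-check calibration over 200 replications of a
30-box dataset, variance-component recovery over 12 seeds of an
8-replicate × 200-box design, and a 10,000-draw parametric bootstrap
against Fieller.  Coverage bands (92–98% for nominal 95%) and recovery
bands (≥90% of seeds within 10%) are the package's own acceptance
guarantees for those sizes.

## Known limitations

* Lethal-time inversion uses fixed-effect coefficients; population-level
  (marginalized over random effects) lethal times would be slightly
  larger and are not implemented.
* The IPPC treated-number variant approximates a convention whose exact
  constant is not restated here; it is labelled approximate in outputs.
* `dispersion_check` simulates from the fixed-effects part of the fitted
  model only, so it tests the observation model conditional on the mean
  structure, not the random-effect distribution.
* Family-wise (simultaneous) lethal-time intervals across stages are out
  of scope, as are dose metameters other than time.
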