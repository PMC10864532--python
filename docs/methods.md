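# Methods

This note documents the models implemented in `lungeud`, their assumptions,
the tunable parameters, what the synthetic cohort generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Dose-volume histograms

All computation happens on the differential DVH: fractional volumes `v_i`
(summing to 1) on half-open dose bins `[edge_i, edge_{i+1})` with the bin
midpoint as representative dose `d_i`, in Gy. Cumulative curves follow the
planning-system convention `V(d)` = fraction receiving ≥ `d`; the midpoint
rule minimizes binning bias for smooth curves. Readers convert units via an
explicit flag (`dose_unit="cGy"` divides doses by 100) — never by magnitude
guessing. The whole-lung and affected-lung DVHs are independent inputs for
real data; no attempt is made to derive one from the other outside the
synthetic generator. DICOM-RT parsing and voxel-level dose grids are out of
scope: everything is evaluated at DVH-bin resolution.

## Generalized EUD and the α sweep

`EUD(α) = (Σ v_i max(d_i, floor)^α)^(1/α)` is evaluated in log space
(`logsumexp`) so exponents up to ±50 are stable; α = 0 uses the
geometric-mean limit. The fractional-volume form is the only one computable
from DVH exports; it coincides with the voxel form when voxels have equal
volume. Consequently `EUD(1)` equals the mean lung dose *exactly* on the
same binned data — a correlation below 1 between the two on real cohorts
indicates they were computed from different representations of the dose
distribution.

**Dose floor** (default 0.01 Gy, configurable and logged): representative
doses are floored before negative powers so cold bins do not drive
`EUD(α<0)` to zero. With the floor, `EUD(α → −50)` converges to the minimum
*effective* (floored) dose. The exact power-mean bounds
`d_max · v_max^{1/α} ≤ EUD(α) ≤ d_max` (α > 0, symmetrically for α < 0) are
what the property tests assert; the extreme-α EUD is within 1% of the
extreme dose only when that dose's bin carries most of the volume.

The sweep grid is ±50 with unit steps outside [−5, 5] and 0.1 steps inside —
fine resolution where a parallel organ's exponent lives. `α*` is the grid
argmax of the relative group difference `R(α)`; exact ties (e.g. identical
group DVH multisets, or cohorts of uniform-dose patients for which EUD is
α-independent) break toward the smallest |α|, then toward negative α. The
tie rule is this package's convention; a unique empirical peak never invokes
it.

A property worth knowing when interpreting `α*`: because `R(α)` normalizes
the group difference by the α-dependent mean EUD, its argmax is *not* an
unbiased estimator of the exponent driving the risk. On synthetic cohorts
whose labels are driven by `EUD(0.3)` the peak sits systematically a few
tenths below 0.3 (and about one unit below when the risk is driven by
`EUD(1)`), while still discriminating clearly between candidate exponents.
The recovery tests therefore assert agreement within one coarse grid step
(±1.0), which holds in ≥ 18/20 seeds at n = 500.

## NTCP models

**LKB probit.** The tolerance dose scales with the effective volume by the
power law `TD50(veff) = TD50 · veff^{-n}`, with
`veff = Σ v_i (d_i/d_ref)^{1/n}`, and the complication probability is
`Φ(t)` via the error function (quadrature of the probit integral is used
only as a test oracle). Two assemblies of `t` are provided behind
`formula_mode`:

- `printed` (default): `t = (d_ref − TD50·veff^{-n}) / (m · TD50·veff^{-n})`
  with `veff` taken at `d_ref`. Default parameters TD50 = 24.5 Gy, m = 2,
  d_ref = 2 Gy, n = 1.
- `standard`: the classical Kutcher–Burman reduction — the DVH is reduced at
  the maximum bin dose `D_max`, and
  `t = (D_max − TD50·veff^{-n}) / (m · TD50·veff^{-n})`, so a whole organ
  uniformly at TD50 (veff = 1) sits exactly at 50%.

Both modes are kept because the printed parameterization is what the
defaults reproduce, while the standard reduction is the form with the
textbook 50% fixed point. Note the defaults are *not* mutually consistent as
slope parameters: the probit/logistic conversion is `γ₅₀ = 1/(m√(2π))`, so
m = 2 corresponds to γ₅₀ ≈ 0.20, not 2 (classically m ≈ 0.1–0.4 for lung).
The conversion helpers are asserted in tests; the defaults are left exactly
as configured. `n` defaults to 1, the parallel-organ convention for lung,
and is configurable and echoed in all reports.

**EUD-calibrated logistic.** `NTCP = 1/(1 + (TD50/EUD)^{4γ₅₀})`: 0 at
EUD = 0, 0.5 at TD50, strictly increasing, with normalized slope
`d NTCP/d ln D |_{TD50} = γ₅₀`. The EUD entering this model is taken at
α = 0.3 (the pipeline's operating exponent) for the respective lung. With
TD50 = 24.5 Gy and whole-lung EUD(0.3) around 5–6 Gy, the whole-lung
probabilities are numerically tiny (≈10⁻⁵); published per-patient values of
a few percent for this quantity cannot be reproduced from the equation at
face value, and no hidden rescaling is applied here. Fitting TD50/m/n to
outcome data and fractionation (EQD2) corrections are out of scope — all
parameters are fixed inputs.

## Statistical chain

- **Feature table**: V5–V30 (% of whole lung), MLD and lung EUD in cGy
  (mirroring clinical reporting), PTV-to-lung volume ratio, the four NTCP
  variants (`sick` = affected lung, `total` = whole lung) and the physical
  composite `MLD[cGy] · (V5/100)(V10/100)(V20/100)(V30/100)`. That unit
  convention is the one under which the composite's two group means (≈6.4
  and ≈3.3 at the reference group statistics) bracket the 6.075 operating
  cutoff; alternative conventions are off by orders of magnitude.
- **Group tests**: independent two-sample t-test, pooled-variance Student by
  default with Welch available; sign convention
  `t = (mean_non-RP − mean_RP)/SE`, so dose metrics elevated in the RP group
  carry negative t. No multiple-testing correction is applied (raw p < 0.05
  screening).
- **Logistic regression**: maximum likelihood via Newton iteration
  (tolerance 1e-8, ≤100 iterations). Clinical units span five orders of
  magnitude, which makes the raw-scale Hessian numerically singular, so the
  fit runs on z-standardized features and the estimate and covariance are
  mapped back exactly (the MLE is invariant under linear reparameterization);
  coefficients are reported in input units with `Wald = (B/SE)²`. Perfect
  separation and non-convergence raise errors rather than returning silent
  output. (A Wald statistic is a squared quantity; a negative "Wald" value
  in a published table is a typographical artifact this package cannot
  reproduce.)
- **ROC**: empirical curve via scikit-learn; the AUC equals the Mann-Whitney
  concordance probability with tie correction (asserted against brute-force
  pair counting). Operating cutoffs maximize Youden's J under the
  "positive if score ≥ cutoff" rule and are reported as the midpoint between
  the optimal threshold and the next score below it; 95% CIs use DeLong's
  structural-components variance (both method choices are this package's,
  made where no method was prescribed). Stratification splits at a cutoff
  into low (<) and high (≥) risk groups and emits per-group distribution
  summaries split by outcome; an empty group is reported, not an error.

## Classifier comparison

Unstated hyperparameters are fixed and logged: SVM with RBF kernel, C = 1,
γ = "scale"; CART decision tree with max depth 3 (guarding small validation
splits against trivial overfit); KNN with k = 5; unpenalized logistic
regression. Features are z-standardized with statistics from the training
data only (inside each CV fold), as SVM/KNN require. The 70/30 split is
stratified and seed-deterministic; model selection uses 5-fold stratified CV
inside the training split, and both the fold-averaged CV AUC and the
refit-on-full-training train/validation AUCs are emitted, since either may
be the quantity a study reports. SVM and logistic models are ranked by their
decision function; tree and KNN by predicted probability. The "without EUD"
predictor set is {physical composite, PTV-to-lung ratio, LKB NTCP sick,
LKB NTCP total}; "with EUD" adds {lung EUD(0.3), EUD-NTCP sick}. The
EUD-NTCP of the whole lung is excluded from the ML feature sets (it adds no
independent signal at these parameter values). Decision curves use
`NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t)` with treat-all/treat-none references;
calibration curves use quantile bins with tie-collapsed bins merged.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Each patient draws a dose-burden component (RP-like with
probability equal to the target incidence, default 0.286) and a metric
vector (V5, V10, V20, V30 in %, MLD in cGy) from a multivariate normal with
that component's means and SDs (defaults: the reported group statistics of
the modelled 77-patient VMAT cohort) and AR(1) correlation 0.9 between
adjacent metrics; draws violating `V5 ≥ V10 ≥ V20 ≥ V30 > 0` are rejected
and resampled. A cumulative DVH is then fit from the two-parameter
Weibull-type family `V(d) = exp(−(d/λ)^k)`, truncated at the 66 Gy
prescription dose and discretized on 0.5 Gy bins. The fit (linearized
closed-form start plus damped Gauss-Newton in V-space, verified against an
independent optimizer) uses only the four V-metrics: two parameters cannot
also be pinned to MLD, so **MLD is emergent**, typically landing 5–10%
above the component's nominal value because the family's tail is heavier
than real lungs'. Draws whose achieved V-metrics deviate by more than 3
percentage points are logged and flagged per record
(`covariates["fit_max_v_err_pp"]`); with the RP-group SDs ≥ 95% of draws fit
within tolerance, while the non-RP group's roughly doubled SDs produce
~18% off-family draws — a known limitation of the two-parameter family.

The affected-lung DVH reweights whole-lung bins by `v_i (d_i/d_max)^{tilt−1}`
(default tilt 2.0 — a value unconstrained by any reported affected-lung
summary and therefore arbitrary); the ipsilateral lung thus concentrates at
higher doses and its features become correlated, noisier carriers of the
same dose signal. Organ volumes are lognormal around the cohort means; arc
angles are normal. Labels are Bernoulli draws from
`P = expit(β₀ + β₁·x)` with `x` the whole-lung EUD(risk_alpha) in Gy
(default α = 0.3) or, for `risk_shape="hinge"`, its positive excess over the
cohort median — a nonlinear dose-risk relation used by the designed
feature-set comparison. `β₁` (`risk_log_or`) defaults to 1.5 per Gy, about
2.5 log-odds per EUD standard deviation — a strong dosimetric effect
consistent with the large group separations the defaults encode; `β₀` is
calibrated by root finding so the mean event probability matches the target
incidence within 1e-4. All randomness flows from one seeded generator;
cohorts are bit-reproducible per seed.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: anatomy and arc geometry (no SAA effect by
construction), clinical covariates, inter-metric structure beyond AR(1),
DVH shapes outside the Weibull family (real cumulative curves can be
multimodal near target volumes), and any dose-response mechanism beyond the
single latent logistic risk. Tests demonstrate that the pipeline recovers
what the generator planted — not that lung EUD predicts pneumonitis in any
particular clinic's population.

## Problem sizes and determinism

The validation suites use sizes chosen to make their statistical assertions
stable: 200 random DVHs for the EUD property suite, n = 500 cohorts × 20
seeds for α-recovery, n = 400 cohorts × 100 seeds for the feature-set
comparison, n = 2000 for logistic coefficient recovery and n = 5000 for
calibration. Every stochastic operation takes an explicit seed and is
reproducible bit-for-bit given (seed, configuration); CLI stages rerun to
byte-identical numeric outputs.
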