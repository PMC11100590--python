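# Methods

## Scope and model structure

slicekin models RISC-catalyzed slicing as mass-action kinetics in nM and
seconds. The accepted single-turnover mechanism treats the purified
enzyme preparation as a two-component mixture: a functionally intact
fraction `F_a` whose complex slices at `k_slice`, and a defective
fraction whose complex turns over at `k_phase2`. Both components bind
target with the same bimolecular `k_on`, bounded above by the diffusion
limit (1 nM⁻¹ s⁻¹). This mixture is what makes single-turnover progress
curves biphasic: a fast phase of amplitude ≈ `F_a` and a slow tail that
eventually completes the reaction when `k_phase2 > 0`.

Five alternative biphasic mechanisms (inactive enzyme that binds but
only dissociates; complexes that partition on binding into a
slicing-incompetent state that dissociates, converts, or slices slowly;
and guide unloading that leaves a naked guide blocking the target) are
implemented from their verbal one-line descriptions as minimal ODE
systems, each adding exactly one `k_phase2`-governed transition (the
reconstructions are documented in `models.py`). Variant 4 is
definitionally the accepted structure and delegates to it. Where a
variant leaves re-released target in solution, re-binding is ON; the
alternative (consumed target) would only change late-time behavior for
large defective fractions and is noted here rather than implemented.
These variants exist to demonstrate that progress curves alone cannot
discriminate the mechanisms: fitted to data generated by the accepted
model, all five reach residual norms within 10% of one another (tested).

## Numerical integration

All ODE systems are integrated with a stiff-capable BDF method
(`scipy.integrate.solve_ivp`, `method="BDF"`, analytic Jacobians) at
relative tolerance 1e-6 and absolute tolerance 1e-10. The systems are
solved in reduced form: the linear conservation laws — total target,
total intact enzyme, total defective enzyme — are eliminated
analytically, and [P], [E], [E′] are reconstructed algebraically from
the integrated states. This keeps conserved totals exact to float
roundoff (measured ≤ 2e-16 relative), halves the system size, and
removes the slow conservation drift that integrating every species
separately would allow. Negative concentrations at the round-off scale
are clipped to zero before fractions are formed; negatives beyond
1e3·atol raise an internal-consistency error rather than being silently
absorbed.

## The pseudo-steady-state closed form and its accuracy

The biphasic closed form
`F = F_a(1 − e^(−t/(1/(k_on·E)+1/k_slice))) + (1−F_a)(1 − e^(−k_phase2 t))`
collapses binding and slicing into a single effective rate (the harmonic
mean of `k_on·E` and `k_slice`). It is used only to seed the ODE fit,
because its accuracy degrades when the two rates are comparable: against
the exact solution the worst-case absolute deviation is ≈ 0.06 at
`k_on·E = 10·k_slice`, ≈ 0.02 at a 40-fold ratio, and < 0.01 beyond a
100-fold ratio (the package's tests pin this behavior). Any workflow
needing the closed form as more than an initializer should respect
those regime limits.

## Fitting procedure

Fitting follows a two-stage design. Stage one classifies the dataset:
if the mean fraction sliced differs by more than 0.15 across enzyme
concentrations at any shared time point, association kinetics contribute
substantially ("slow association"), which selects the `k_on`
initialization (0.0167 vs 0.167 nM⁻¹ s⁻¹). Fixed initializations
(`k_slice` 0.0167 s⁻¹, `k_phase2` 3.33e-6 s⁻¹, `F_a` = 0.95 × highest
observed fraction) are refined against the closed form by bounded least
squares (≤ 50 iterations; bounds `k_on` (1e-6, 1), `k_slice` (1e-6, 1),
`k_phase2` (1.67e-6, 1.67e-4), `F_a` (0.3, 0.999)). If that regression
fails the fixed values are used with `F_a` = 0.85; for slow-association
data the fitted `F_a` is scaled by 0.9 to counter the closed form's
plateau overestimate.

Stage two fits the ODE model to the pooled residual vector over all
concentration series (no per-replicate weighting), rate constants in
log10 space, `F_a` linear; bounds `k_on` (0, 1], `k_slice` (0, ∞),
`k_phase2` (1.67e-6, 3.33e-3), `F_a` (0.3, 1.0), ≤ 200 iterations. The
minimizer is `scipy.optimize.least_squares` with the
trust-region-reflective method: scipy's Levenberg–Marquardt does not
accept bounds, and TRF honors the same residual-vector least-squares
contract. The objective treats the per-point absolute deviations as the
residual vector of a summed-squares fit; a robust (`soft_l1`) loss is
exposed as an option for the L1 reading of "absolute deviation".

A parameter is "not confidently fit" when its asymptotic 95% CI spans
more than two orders of magnitude or its estimate sits at a bound. The
fallbacks are ordered: first `k_on` is pinned to the diffusion limit and
the fit repeated; then `k_phase2` is pinned to zero. Constrained
parameters carry no CI and are flagged in the result and in pipeline
reports. Very slow mismatched-target reactions whose plateau cannot be
resolved are fit with the monophasic form `F_a(1 − e^(−k_slice t))`,
`k_slice` initialized at 1.67e-4 s⁻¹ and `F_a` fixed to the value fitted
for the same guide's perfectly complementary target.

Multiple-turnover fits take the four single-turnover constants as given
and fit `k_offP` (log space), `F_max`, and the total enzyme
concentration as a deviation bounded within two-fold of the intended
value. Datasets whose fractions never exceed 0.2 fix `F_max` = 1 and
initialize `k_offP` at 0.0167 s⁻¹; faster datasets initialize `k_offP`
at 0.167 s⁻¹ and fit `F_max` from 0.95 in (0, 1).

## Uncertainty

Default 95% intervals are asymptotic: covariance from the final
Jacobian in transformed (log10-rate) space, ±1.96 SE, exponentiated.
The estimator the original gel-based analyses used is not recorded, so a
residual-resampling bootstrap (refit per resample, percentile interval)
is provided as a cross-check; on representative noisy data the two agree
in log-width to within ~30% (tested). τ_slice intervals are the
reversed reciprocals of the `k_slice` interval. Fold changes between
two fitted `k_slice` values propagate uncertainty in log space:
half-width factor `exp(1.96·√(se_a² + se_b²))` on natural-log SEs;
`fold_change(a,b)·fold_change(b,a) = 1` exactly. Singular covariance
matrices fall back to a pseudo-inverse and mark the interval unreliable.

## Titration, association, thermodynamics

The tight-binding quadratic is implemented as
`F = θ·(1−yint) + yint` with
`θ = (S+T+K_D − √((S+T+K_D)² − 4ST))/(2T)`, `S = stock·DF`, `T` total
target — the only placement of `(1−yint)` that keeps F within
[yint, 1]. Concentrations are reconciled to pM at the fitting boundary
(targets are supplied in nM). Stock significance uses the fit's
asymptotic t-statistic; p > 0.05 triggers the documented fallback to the
sub-saturation (≤ 60% bound) linear regression, whose intercept is left
unconstrained. Association fits use `F = A(1 − e^(−k_on·[RISC]·t))`
(A initialized 0.8 in (0,1), `k_on` 0.0333 in (0,1)); when the first
time point is already ≥ 95% of the fitted plateau the rate is reported
as a lower bound at the diffusion limit.

The mismatch-tolerance sigmoid is fit on log(ratio) with unweighted
residuals (per-point uncertainties are not part of the data contract),
`ΔG°_thres` initialized at 10 kcal/mol and unbounded; R is taken as
1.987204e-3 kcal mol⁻¹ K⁻¹ and T = 310.15 K. Data with no spread in ΔG
raise an unidentifiability error; data pinned at ratio ≈ 1 return a fit
flagged unidentifiable (the threshold runs to −∞ when no barrier is
detectable). The knockdown ceiling formula
`(1/τ_slice)/(ln2/t½ + 1/τ_slice)` is the steady state of
`dM/dt = α − (k_deg + k_s)M`; an explicit ODE oracle verifies it to
1e-6 across a grid.

## Footprinting

Normalization is per-position linear rescaling between the simple means
of quenched (0) and naked-guide (1) anchor lanes; it is invariant to any
positive affine transform applied jointly to a lane and both anchors,
and positions with zero dynamic range are auto-masked. Degradation
bands are corrected by the mean of the two immediate flanking values;
terminal or adjacently flagged positions are masked instead. A
replicate is flagged denatured when strictly more than half of its
unmasked positions lie > 2 SD above the per-position mean of the other
replicates. Unquantifiable positions (salt front, full-length merge,
trimmed isoforms) are represented through the mask, configured per
dataset rather than hard-coded. Masked positions never enter any mean
or SD.

## Synthetic data: what it does and does not emulate

Generators are bit-exact functions of (truth, design, seed). The
default slicing design is a 10-fold enzyme dilution series at 0.33, 3.3
and 33 nM — spanning the 0.09–33 nM range such assays use — against
0.02 nM target, with 12 log-spaced time points from 10 s to ~48 h so
both phases are sampled. Default truth parameters are `k_on` 0.005
nM⁻¹ s⁻¹, `k_slice` 0.01 s⁻¹, `k_phase2` 1e-5 s⁻¹, `F_a` 0.9 —
mid-range values for which association, slicing, and the slow phase all
leave a signature in the data. Measurement noise is additive Gaussian
on the fraction scale (σ = 0.02 by default, clamped to [0, 1]),
matching the approximately homoscedastic error of phosphorimager band
quantification; rate-ratio (thermodynamic) data instead carry
multiplicative lognormal noise. Footprinting lanes are built from
parameterized reactivity templates (central 9–11 and 3′-terminal
exposure in the slicing-competent state; protected seed in the
no-target state) mapped through position-dependent background and
dynamic-range profiles.

The generators do not emulate gel artifacts (band compression, lane
bleed, background gradients beyond the smooth profiles above),
pipetting or timing errors, heteroscedastic noise at the fraction
extremes, target secondary structure, or enzyme inactivation over long
incubations. Passing recovery tests therefore demonstrates estimator
correctness and identifiability under the stated error model, not
robustness to every failure mode of real gels.

With these defaults, a 50-dataset Monte-Carlo study (recomputed by
`scripts/acceptance.py` and the test suite) recovers `k_slice` with a
median relative error of ~3–4% and asymptotic-CI coverage of ~90–94%.

## Known limitations

- No stochastic (Gillespie) simulation, temperature dependence, or
  explicit conformational sub-states; conformational equilibria enter
  only through the thermodynamic sigmoid.
- The closed-form seed is inaccurate near `k_on·E ≈ k_slice` (see
  above); the ODE stage, not the seed, carries the accuracy.
- Asymptotic CIs undercover mildly in small, strongly nonlinear
  datasets; use the bootstrap cross-check when intervals matter.
- Global fitting across guides, model averaging, and Bayesian posterior
  sampling are out of scope.
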