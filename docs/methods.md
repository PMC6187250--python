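# Methods

## Model

The package treats two regional imaging biomarkers — PET binding potential or
SUVR values, used as unitless proxies for the concentration of an underlying
pathological substance — as species in a biochemical reaction in which the
upstream species BP1 drives production of the downstream species BP2:

    a BP1 + Σ_i b_i B_i  →  m BP2 + Σ_j n_j C_j

The bath species `B_i` (reactants already abundant in healthy tissue) and
by-products `C_j` are unobservable; their coefficients are unknown and, under
the reduction below, have no observable consequence.  The reaction speed
follows a power rate law

    d[BP2]/dt = −(m/a) d[BP1]/dt = k [BP1]^x Π_i [B_i]^{y_i}

Reaction orders need not equal stoichiometric coefficients.  When the bath
starts in large excess over BP1 ([B_i]_0 ≫ [BP1]_0) its concentrations are
effectively constant over the observation window and fold into an effective
pseudo-first-order constant k′ = k Π_i [B_i]_0^{y_i}, leaving

    d[BP2]/dt = k′ [BP1]^x,

which is log-linear:  ln(d[BP2]/dt) = ln k′ + x ln[BP1].  The estimators fit
this line; the simulator integrates both the reduced and the full
(bath-depleting) systems so that the reduction's validity can be checked
directly.  Each reaction event consumes bath species with unit stoichiometry
by default (configurable): the simplest choice that still lets the reduction
fail when the bath is scarce.

Assumptions worth keeping in mind: stationary kinetics (k, k′, x constant in
time), a single reaction channel between the pair, and measurements
proportional to concentration.

## Estimation

**Longitudinal.**  Per subject and region, d[BP2]/dt is estimated by finite
differences of the measured downstream series (second-order central stencils
inside, first-order one-sided at the two ends) and regressed, by ordinary
least squares in log-log space, on the upstream values at the same visits.
The slope estimates x, the intercept ln k′.  Nonpositive rate estimates —
which arise from noise and have no logarithm — are dropped and counted, never
rectified, with a minimum of 3 surviving points per fit.  The one-sided
endpoint estimates carry O(h) bias that dominates on short series (the
intended data are 4–8 visits), so they are excluded by default
(`drop_endpoints=False` restores them).  An alternative `midpoint` pairing
regresses interval secant slopes on the geometric mean of adjacent upstream
values; it is exact for x = 1 and x = 2 on noiseless data and is exposed for
sensitivity analysis.  Same-visit pairing is the default.

Subject-level estimates are pooled per region with the closed-form
DerSimonian–Laird random-effects model (weights 1/(se² + τ²)), with a
two-sided z-test of x = 0; an unweighted one-sample t-test is reported as a
robustness line, and Benjamini–Hochberg FDR across regions accompanies the
raw p-values.  Be aware that with ~4 usable points per subject the individual
OLS estimates are heavily dispersed (sampling sd of order 1 at 5% measurement
noise) and attenuated by noise in the regressor (errors-in-variables), so
pooled estimates at n = 50 subjects carry standard errors of roughly 0.1–0.15
and a small downward bias that grows with x; the tests and the acceptance
script measure this honestly rather than hiding it.

**Cross-sectional.**  With one visit per subject, the rate of change is
approximated by the covariate-adjusted slope of the downstream biomarker
against a disease-severity score τ (OLS of value on τ + age + sex +
education, covariates standardized, coefficients not interpreted), separately
per region.  Across regions, ln(slope) is regressed on ln(baseline [BP1]);
the slope of that line is the whole-brain reaction-order estimate — inference
is drawn for the whole brain only, since per-subject rates are not
estimable.  `baseline_bp1` is the mean upstream value over subjects in the
cohort's lowest severity tertile (the observable analog of a baseline
concentration); a concurrent-mean alternative is exposed by flag.  Alongside
the parametric t-test, a seeded sign-flip permutation test (10,000 draws by
default) provides inference free of distributional assumptions across
non-independent regions.  A guard warns when the severity range implies more
than 20% upstream depletion, where the linear-slope approximation degrades.

The across-region regression carries a single intercept ln k′ — it assumes a
rate constant shared across regions.  Region-to-region variation in k′ acts
as scatter around the line and, if correlated with the baseline spread,
biases the order estimate; the benchmark design below deals with this by
construction.

**Direction selection.**  Both causal orderings produce log-linear models of
identical analytical form and identical parameter count (2), so no complexity
penalty applies and the orderings are compared purely by goodness of fit.
The directional score pools subjects by stacking their usable log-points into
one regression per region (subjects share the trajectory up to onset time
shifts, and the rate law is shift-invariant, so under the true direction
their points fall on a single line) and averaging the stacked r² over
regions; per-subject r² from 4-point regressions proved far too volatile to
compare (sd of a median-based margin ≈ 0.1–0.2 across cohorts, swamping any
fixed dead band).  When the nominally downstream series is actually depleting,
its finite-difference rates are predominantly negative; the fit then uses
|rate| with a sign flag rather than discarding nearly all points, so the
comparison tests fit quality, not data retention.  A direction is selected
only when the margin r²_forward − r²_reverse clears a dead band of 0.01 *and*
a seeded bootstrap (subjects resampled for longitudinal data, regions for
cross-sectional, resamples shared between the two directions) puts the
observed sign in doubt with probability < 0.05 (one-sided); otherwise the
report is *indeterminate*.  The construction is exactly antisymmetric under
relabeling of the two biomarkers.  Measured operating characteristics at the
benchmark design: 100% correct selection on noiseless cohorts, ~97% at 5%
noise, and ~100% indeterminate on flat-plus-noise cohorts.

## Synthetic cohorts

The generator emulates multi-subject, multi-region, two-tracer concentration
panels.  Defaults (all configurable through `CohortDesign`):

| parameter | default | meaning |
|---|---|---|
| visit grid | 0, 2, …, 10 y | biennial imaging over a decade |
| k′ | 0.05 /y | ~40% upstream conversion over the window |
| x | 1.0 | first-order kinetics |
| [BP1]_0, [BP2]_0 | 1.0, 0.1 | SUVR-like baseline levels |
| onset sd | 2 y | subject onset offsets (time shifts along one curve) |
| noise | 5% log-normal | multiplicative measurement noise |
| covariate effects | ≤ ~3% additive | age/sex/education confounds |
| severity τ | uniform 0–10 | one-visit disease stage, time = α·τ + onset, α = 1 y/unit |

Noise is multiplicative log-normal because the estimator is a log-scale
linear model; an additive mode exists for stress-testing.  Subject
heterogeneity enters only through onset offsets, which leave the longitudinal
estimator unbiased (the rate law is autonomous) but degrade the
cross-sectional severity-to-time mapping — exactly the contrast the
consistency check exploits.  Covariate effects are additive on the measured
scale and small, acting as removable confounds.  One master seed expands into
per-subject streams (`SeedSequence` spawn keys), so growing a cohort never
reshuffles existing subjects and every table is byte-reproducible.

The cross-sectional benchmark design uses 10 regions whose baseline upstream
concentrations span 4× on a geometric grid and whose k′ multipliers span 4×
on a mirror-symmetric grid.  The symmetric log-k′ grid is exactly orthogonal,
in sample, to the antisymmetric log-baseline grid — so rate-constant
heterogeneity (and any function of it, such as onset-induced attenuation that
varies with k′) contributes scatter but zero confounding to the order
estimate.  This is an orthogonal-design choice, made so the benchmark
isolates the estimator's ability to recover x; real cohorts offer no such
guarantee, and a correlation between regional kinetics and regional baseline
load would bias the cross-sectional estimate.

What the generator does *not* emulate: missing data and dropout, scanner
drift, per-subject rate constants, mixed pathologies, nonlinear
severity-to-time maps.  Passing tests therefore demonstrate correctness of
the machinery under the model's own assumptions, not robustness to every
failure mode of real imaging data.

## Numerical choices

Integration uses an adaptive stiff-capable solver (LSODA) at rtol 1e-8 /
atol 1e-10, with concentrations clipped at 0 after evaluation to guard the
power law's domain; closed-form checks (exponential for x = 1, rational for
x = 2) agree to better than 1e-8 relative, and a fixed-step Euler oracle at
dt = 1e-4 agrees to 1e-4.  Finite differences are exact on quadratics at
interior points.  Noiseless fits reproduce x to machine-level accuracy with
analytic rates and to <1e-3 with finite differences on dense grids.
Degenerate inputs (constant series, equilibrium k′ = 0, rank-deficient
designs, fewer than 3 usable points or regions) yield flagged results, not
exceptions, so batch runs carry partial failures along.  Within-cohort
generation solves each region's trajectory once on the union of subject time
points (all subjects lie on one curve per region), which makes large cohorts
cheap without changing any value.

## Problem sizes used by the validation suite

The acceptance script and test suite run at desk scale, sized to the study
conditions: 50-subject longitudinal cohorts (6 visits), 200-subject
cross-sectional cohorts (10 regions), 50–100 Monte-Carlo replicates for
rates, 20–50 seeds for consistency sweeps.  These sizes reproduce the
reported operating characteristics; larger runs only sharpen the same
numbers.

## Known limitations

- Per-subject estimates from short series are information-starved; the
  pooled reaction order carries se ≈ 0.1–0.15 at the benchmark design and a
  mild attenuation bias.  Longer follow-up or denser visits help more than
  more subjects.
- The cross-sectional estimator inherits the assumptions of a shared
  trajectory, a linear severity-to-time map, and a shared k′ across regions;
  violations bias it in ways the consistency report only partially flags.
- The ln transform of finite-difference rates is asymmetric in noise; rates
  near zero produce heavy left tails.  Dropping nonpositive rates (counted)
  is the chosen, documented remedy.
- Pairwise orderings only; no reaction networks, no latent disease-time
  estimation, no image-space processing.
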