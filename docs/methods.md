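# Methods

## The kinetic model

A gene's premature RNA P and mature RNA M follow the linear two-compartment
system dP/dt = k1(t) − k2(t)·P, dM/dt = k2(t)·P − k3(t)·M, with k1 the
synthesis rate (RNA units·h⁻¹) and k2, k3 first-order processing and
degradation constants (h⁻¹). The model assumes a single well-mixed pool per
species, first-order processing and decay, and no feedback of abundances on
rates. Concentrations are in arbitrary expression units; nothing enforces a
particular normalization, and the chi-squared objective is invariant under
a joint rescaling of a species' data and predictions.

Each rate is one of three analytic forms: constant (1 parameter), sigmoid
(4: start level h0, final level h1, transition time t1, slope β) or impulse
(6: a product of two sigmoids sharing one slope, normalized by 1/h1, adding
a second level h2 and time t2). The impulse form is the standard
product-of-sigmoids parameterization used for expression time courses; with
h2 = h1 its second factor is identically h1 and it collapses exactly to the
sigmoid, which in turn collapses to the constant when h1 = h0. These exact
nestings are what model selection and warm-starting rely on. Level
parameters and β must be strictly positive and t1 < t2, so every form
evaluates to a finite positive rate at any finite time.

Time is linear, in hours; no log-time warping is applied.

## Solving the ODE

Trajectories start, by default, from the equilibrium implied by the rate
values at the first requested time (P = k1/k2, M = k1/k3): perturbation
experiments begin from a settled state, and all-constant models therefore
produce exactly flat profiles. An explicit (P0, M0) override exists for
studying relaxation, mainly in tests.

Two integration paths exist:

* **Adaptive (default)**: LSODA with rtol 1e−6, atol 1e−9, dense output at
  the requested times and a maximum step of 1/25 of the span (so narrow
  transitions are not stepped over). Rates spanning orders of magnitude
  make the system stiff; LSODA switches methods automatically. Verified
  against the independently implemented closed-form constant-rate solution
  (including the degenerate k2 = k3 branch, entered below a relative
  eigenvalue gap of 1e−8, where the secular τ·e^(−kτ) term replaces the
  ill-conditioned two-exponential difference).
* **Fixed-step exponential midpoint (fitting path)**: over each substep
  the rates are frozen at the midpoint time and the resulting
  constant-coefficient system is advanced with its exact solution. The
  scheme is unconditionally stable, exact for constant rates, second-order
  for varying ones; substeps are capped at 0.25/β for the steepest slope
  and at least 150 per span. Its error (≲1e−3 relative at default slopes)
  is far below replicate noise, and because every candidate class is scored
  through the same path, between-class χ² comparisons are unaffected.
  Roughly three orders of magnitude faster than the adaptive path, which is
  what makes multi-start fitting and the resampling experiments practical.

Outputs are clipped at zero (integrator undershoot is at roundoff level).

## Fitting

The objective is weighted least squares with weights equal to the inverse
variance of the replicate mean, sd²/n_replicates, summed over premature,
mature and (in nascent-RNA mode) synthesis observations; under Gaussian
replicate error the minimum is a chi-squared statistic with
dof = observations − free parameters. Standard deviations are floored at
max(1e−6, 1% of |mean|) to keep degenerate replicates from producing
infinite weights; floored points are logged.

Optimization runs in a transformed space: levels and β as logarithms
(positivity for free), transition times unconstrained but quadratically
penalized outside the observed window extended by one span on each side,
and the impulse ordering kept by optimizing t1 and log(t2 − t1). Runaway
log coordinates beyond e²⁵ are softly penalized and hard-clamped at e⁵⁰
to avoid overflow.

Multi-start: (1) a data-driven start — k1 from the synthesis observations
(or anchored at k3 = 1 h⁻¹ without them), k2 and k3 from the steady-state
relations at the profile's ends, transition times at the steepest observed
change; (2) a flat start embedding the constant-rate estimate into the
class's forms; (3) seeded log-normal jitters (sd 0.5 in log coordinates,
span/6 on times) of the data-driven start, five starts in total by
default. Nelder-Mead (adaptive simplex, xatol 1e−5, fatol 1e−7, default
budget 5000 evaluations per start) is the default optimizer, BFGS with
numerical gradients the alternative. If the best start stops on its budget
a single restart from the incumbent is run — a fresh simplex at a
near-optimum typically converges in few iterations. All randomness flows
from the explicit seed; identical seeds and inputs give bit-identical
results.

One exact shortcut: a single steady-state time point with observed
synthesis and an all-constant class is three equations in three unknowns
and is inverted in closed form (k1 = S, k2 = S/P, k3 = S/M).

## Goodness of fit, selection, intervals

p = 2·min(F(χ²; dof), 1 − F(χ²; dof)) capped at 1 — two-tailed because a
fit far better than the stated variances allow indicates misspecified
errors just as a poor fit indicates a wrong model. AIC = χ² + 2k treats χ²
as −2·log-likelihood up to a data-only constant, which cancels when
comparing classes on the same data — the only use made of it. Ranking is
by ascending AIC with deterministic tie-breaks (fewer parameters, then
class code). Classes are fitted simplest-first and each richer class's
multi-start includes the best embeddable simpler fit, so nested classes
can never score worse than their parents beyond optimizer tolerance.

Confidence intervals are profile likelihood rather than a Hessian
approximation — impulse parameters are too nonlinear for a quadratic
expansion. For each parameter the profiled χ² (all others re-optimized,
warm-started) is scanned outward by doubling steps and the crossing of
χ²_min + 3.84 (95%, 1 dof) is bisected to 1e−3 in the transformed
coordinate. Profiles still flat five log-units out (a factor ~150) are
flagged unbounded on that side.

## Synthetic data

The generator defines the package's study conditions: 12 time points over
16 h (denser early: 0, 0.5, 1, 2, 3, 4, 6, 8, 10, 12, 14, 16), 3
replicates, Gaussian noise with CV 0.10 truncated at zero (truncations
logged). Ground-truth models draw baseline levels log-uniformly at
plausible mammalian scales (k1 ∈ [0.5, 50] units·h⁻¹, k2 ∈ [0.5, 20] h⁻¹,
k3 ∈ [0.05, 5] h⁻¹); variable rates move by a 2–4× fold (log-uniform,
direction random) with slopes in [0.5, 2] h⁻¹ and first transitions in the
first half of the window. Independent draws of the two levels would often
give near-unity fold changes — a "regulated" rate that does not actually
change — so the fold is drawn explicitly.

Profiles store either the across-replicate sample sd (default — what a
pipeline computes from real replicates) or the noise law's exact sd
(`sd_mode="exact"`). The calibration, coverage and selection experiments
use exact sds: with 3 replicates the sampling error of the empirical sd
makes inverse-variance weights heavy-tailed (the expectation of σ²/s²
diverges below 4 replicates), and no chi-squared statistic could be
calibrated against that; the exact-sd setting tests the statistic itself.
The recovery experiments keep the empirical default, where the variance
floor contains the occasional degenerate replicate set.

What the generator does not emulate: count noise (sequencing depth),
gene-length and library-size biases, intron/exon mis-assignment, and
correlated replicate error. Passing tests therefore demonstrate the
estimator's correctness under its own error model, not robustness to
quantification artifacts upstream.

## Validation experiment sizes

Chosen to characterize the statistics while keeping the whole suite at a
few minutes on one core: 1000 random triples for steady-state exactness;
100 random constant-rate models (one in ten exactly degenerate) for the
ODE-oracle comparison; 50 seeded repetitions each for constant/sigmoid
recovery (CV 0.05) and for model selection over {no-reg, s, sd, sp} at CV
0.10 with the true class cycling; 200 repetitions for p-value calibration
(Kolmogorov–Smirnov distance to uniform) and for 95% interval coverage of
the synthesis level on the constant-rate fixture (3, 1.2, 0.4).

## Known limitations

* Without nascent-RNA observations the absolute scale of k1 is only weakly
  identified from P/M dynamics (flat data leave only the ratios k1/k2,
  k1/k3); recovery claims hold for the nascent mode.
* The impulse 1/h1 normalization is one of several parameterizations in
  circulation; fitted time courses are comparable across conventions, the
  raw h1 values are not.
* Profile-interval bounds for impulse t2 are reported at the re-optimized
  t1 of the crossing point, since t2 is profiled through log(t2 − t1).
* AIC here omits the Gaussian normalization constants; only differences on
  the same data are meaningful, never absolute values across datasets.
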