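# Methods

## Model

The MMCP model treats a regularized track as a sequence of step lengths
r_t (exponential) and turning angles phi_t (von Mises, mean direction 0)
whose parameters switch between a resident regime (rho_0, kappa_0) and a
migratory regime (rho_0 + rho_n, kappa_0 + kappa_n) on c half-open
intervals (t_{2n-1}, t_{2n}]. The per-location negative log-likelihood is

    log(rho) + r_t / rho + log(2 pi I_0(kappa)) - kappa cos(phi_t),

with terms dropped where the underlying metric is undefined (first fix has
neither metric; the second only a step length; steps spanning missing fixes
are masked). Step lengths and turning angles are assumed independent and
serially uncorrelated; both assumptions are simplifications of real
telemetry and are the price of closed-form profile estimates.

Fixing the mean direction at zero follows the kappa*cos(phi) form of the
likelihood; the concentration MLE therefore inverts A(kappa) =
I_1(kappa)/I_0(kappa) against the segment mean cosine (a generic von Mises
fitter that also frees the mean direction is a defensible alternative and
would give slightly different kappa estimates on tortuous tracks).
Migratory increments are truncated at zero, encoding the hypothesis that
migration is faster and straighter; consequently R = (rho_0 + rho_1)/rho_0
is always >= 1.

## Parameter estimation

With change-points fixed, profile MLEs are: rho_0 = mean non-migratory step
length; kappa_0 = A^{-1}(mean non-migratory cos phi), solved by a seeded
Newton iteration on exponentially scaled Bessel ratios (verified against
brute-force likelihood maximization to 1e-4 and solved internally to ~1e-12);
per-period increments are the period MLE minus the baseline, truncated at 0.
kappa is capped at 500 — the MLE diverges when all pooled angles coincide,
and 500 is far beyond any biologically plausible concentration while
remaining safe on the log scale. Candidates leaving any pool with fewer
than `min_segment = 2` valid step lengths or no valid turning angle are
infeasible (skipped), so segment means are always defined.

The change-points are found by direct search: evaluate the profile NLL on a
(2c)-dimensional lattice of resolution 14 sampling intervals, carry the 5
lowest-NLL tuples to lattices of 7, 3, and 1, each restricted to windows of
+/- (previous resolution) around a carried tuple (the ceiling of the ratio
is used so the finer lattice always covers the coarse cell), and return the
best candidate evaluated anywhere. Ties break lexicographically on
(t_1, t_2, ...), making the search fully deterministic. Dynamic-programming
segmentation is inapplicable because distinct segments share parameters, so
segment costs are not independent. An exhaustive search over the finest
lattice (guarded at 10^6 candidates) serves as an exact reference; on
strong-switch series the staged search matched it in 100/100 seeded
replicates. Candidate batches are evaluated from prefix sums of the
sufficient statistics, so a stage costs O(n + m) rather than O(n m).

Durations are constrained strictly (t_2 - t_1 > min_duration, default 7
sampling intervals; use 14 for slower migrants), mirroring the biological
floor on meaningful migrations. AIC uses k = 4c + 2 (change-points are
counted as parameters; k = 2c + 4 when a single migratory increment is
shared across periods).

## Bootstrap

Confidence intervals are parametric-bootstrap percentiles: replicates
inherit the observed series' exact timestamps and validity masks (so the
missingness pattern is replicated), are drawn from the fitted model with
sub-seed seed + i, refitted with the identical search configuration
anchored to the observed time bounds, and the 2.5%/97.5% quantiles of the
feasible refit estimates are reported. Infeasible refits are counted and
excluded, never imputed; results with > 50% failures are flagged
unreliable. Wald and profile intervals are unavailable because the
likelihood is discontinuous in the change-points.

## Simulators

The simulators generate the validation conditions: 300-timestep paths,
migration on (100, 200], degraded by 1/12 dropout (the first location is
always kept as an anchor) and Gaussian jitter of per-axis variance sigma_e
in {0, 1, 25} — sigma_e = 25 gives a mean Rayleigh displacement of
5 sqrt(pi/2) ~ 6.27 spatial units, larger than a typical resident step.

The correlated-velocity model is a 2D Ornstein-Uhlenbeck velocity process
with timescale tau and per-axis stationary standard deviation
sigma = nu sqrt(2/pi), so nu is the stationary *mean speed* (the speed is
Rayleigh(sigma)); an RMS-speed parameterization is the main alternative and
would differ by a factor sqrt(pi/2). Velocities follow exact OU transitions
on substeps of 0.1 time units; positions are trapezoidal integrals of the
velocity. At a speed switch the current velocity is rescaled by the ratio
of stationary standard deviations (direction preserved, no boundary
transient); at a pure timescale switch it is carried unchanged. The three
schedules are: speed switch (nu 1 -> 5 -> 1, tau = 2), timescale switch
(nu = 1, tau 2 -> 20 -> 2; the instantaneous-speed marginal is invariant
across phases, only directional persistence changes), and bias switch — a
discrete biased correlated random walk with Weibull(1, 1) steps, turning
concentration 0.5, and heading mean equal to the direction of
A u(bearing-to-attraction) + (1 - A) u(previous heading), the standard BCRW
construction; the attraction point jumps from (0, 0) to (50, 0) and A from
0.5 to 0.9 during migration, leaving both marginals the model sees
unchanged.

What the simulators do *not* emulate: state-dependent fix failure,
autocorrelated or heavy-tailed measurement error, behavioural states beyond
a binary migratory switch, tortuosity-speed cross-correlation, and 3D
movement. Passing the validation suite therefore demonstrates correct
recovery under the stated generative conditions, not performance guarantees
on arbitrary field data — in particular the bias-switch generator is an
intentional failure mode (neither step lengths nor turning angles change,
so the model's estimates there are essentially arbitrary, and the harness
only checks that it runs and reports).

## Evaluation

Classification profiles are pointwise means of the fitted indicator across
replicates; change-point errors are summarised by median and median
absolute deviation (robust to the bias-switch failures). Non-migratory
range overlap for c = 2 fits uses the closed-form Bhattacharyya affinity
between bivariate Gaussians fitted to each range's locations (sample mean
and covariance): BA = exp(-D_B) with the standard Gaussian Bhattacharyya
distance. This is a deliberate surrogate for movement-model-based kernel
overlap: it is exact for the Gaussian range model, fully testable by
quadrature, and adequate for judging whether ranges are spatially disjoint;
it will understate overlap for strongly non-elliptical ranges. No numeric
BA threshold is imposed — values are reported, the behavioural call is left
to the analyst.

## Problem sizes and defaults

Validation uses 50 replicates per generator for change-point recovery
(medians of t-hat), 100 series of length 120 for search/oracle
equivalence, and 100 datasets x 50 bootstrap paths for CI coverage of the
migration onset (nominal 95%, accepted band 85-100/100 by binomial
tolerance; the generating model uses rho_0 = 1, rho_1 = 4, kappa_0 = 0.5,
kappa_1 = 2, matching the strong speed-switch regime, with kappa_0 = 0.5
chosen to match the simulators' baseline angular concentration). Bootstrap
defaults to 100 paths per dataset for applied use; re-running with
different seeds and comparing intervals is the recommended stability check.

## Known limitations

- Exponential steps and von Mises turns are fixed in this version; gamma or
  Weibull steps and wrapped-Cauchy turns are natural extensions.
- c must be supplied; model selection across c is by AIC comparison only.
- The search is exact only in the limit of a smooth NLL surface across
  change-points; the exhaustive oracle is available (and cheap for c = 1 on
  year-scale daily data) when certainty is required.
- Tracks must be in planar projected coordinates; geographic coordinates
  must be projected upstream.
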