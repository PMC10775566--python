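# mmcp — migration timing from step lengths and turning angles

`mmcp` estimates **when an animal's migration begins and ends** from
regularized tracking data (e.g. daily GPS fixes). It is aimed at movement
ecologists who have a projected, roughly evenly sampled track and want
interpretable estimates of migration phenology together with honest
uncertainty, plus a measure of *how* movement changed during migration.

## The model

Movement is summarised by two per-step metrics: the step length
*r<sub>t</sub>* (Euclidean displacement between consecutive fixes) and the
turning angle *φ<sub>t</sub>* (signed change of heading over three
consecutive fixes). The multi-metric change-point (MMCP) model assumes

- *r<sub>t</sub>* ~ Exponential with mean ρ₀ + I(t)·ρ₁,
- *φ<sub>t</sub>* ~ von Mises(0, κ₀ + I(t)·κ₁),

where the migratory indicator I(t) = 1 exactly on (t₁, t₂] (more generally
on *c* intervals (t₂ₙ₋₁, t₂ₙ]). Migration is hypothesised to be faster
(ρ₁ ≥ 0) and straighter (κ₁ ≥ 0) than resident movement; negative profile
estimates are truncated at zero. With the change-points fixed, the (ρ, κ)
maximum-likelihood estimates are closed-form/1-D profile solutions (segment
means; inversion of I₁/I₀ against the segment mean cosine), so fitting
reduces to a search over change-points. Because the likelihood is
discontinuous in t, the change-points are located by a multi-resolution
grid search (lattices of 14, 7, 3, 1 sampling intervals, carrying the five
best candidates between stages), and confidence intervals come from a
parametric bootstrap: simulate series from the fitted model onto the
observed time skeleton, refit, and take 2.5%/97.5% quantiles. Competing
numbers of migrations (c = 1 vs c = 2, e.g. to detect stopovers) are
compared by AIC with k = 4c + 2. The statistic R = (ρ₀ + ρ₁)/ρ₀ summarises
the migratory speed-up.

The package also ships the generative movement simulators used to validate
the method — a correlated-velocity (Ornstein–Uhlenbeck) process with a
speed or autocorrelation-timescale switch, a biased correlated random walk
with an attraction-point switch, and a telemetry degradation model
(random dropout, Gaussian jitter) — plus an evaluation harness
(classification profiles, change-point errors, Gaussian Bhattacharyya
overlap of non-migratory ranges).

## Worked example

```python
import numpy as np
from mmcp import MMCPChangePoint, compute_steps, bootstrap_cis
from mmcp.simulate import (speed_switch_spec, simulate_cvm_switch,
                           degrade_track, DegradationSpec)

# a 300-step track whose mean speed rises 1 -> 5 -> 1 at times 100 and 200,
# with 1-in-12 missing fixes
lt = simulate_cvm_switch(speed_switch_spec(), seed=1)
lt = degrade_track(lt, DegradationSpec(p_miss=1/12, sigma_e=0.0), seed=2)
steps = compute_steps(lt.track)

est = MMCPChangePoint(c=1).fit(steps)
print(est.changepoints_)          # [100. 200.]
p = est.params_
print(p.rho0, p.rho_mig[0])       # 0.899  3.894   (true means: 1 and 4)
print(est.speed_ratio_[0])        # 5.33            (true R = 5)

res = bootstrap_cis(steps, est.fit_, n_paths=100, seed=0)
print(res.ci["t1"], res.ci["t2"]) # (91.0, 105.0)  (191.95, 204.0)
```

The fitted change-points land exactly on the true switch times; the
baseline and migratory step-length means recover the generating values
(0.90 and 0.90 + 3.89 ≈ 4.8 vs the true 1 and 5), and both bootstrap
intervals cover the truth.

The same workflow is available from the shell:

```bash
mmcp simulate --model speed --reps 50 --seed 1 --out sims/
mmcp evaluate --tracks sims/ --c 1 --out results/speed
mmcp fit --input steps.csv --c 1 --min-duration 7 --out fit.json
mmcp bootstrap --fit fit.json --input steps.csv --n 100 --seed 0 --out ci.csv
```

For real tracks, `mmcp prep` reads a CSV of (id, timestamp, x, y, optional
hdop/vdop) in projected kilometres, applies the DOP filter, rarefies to one
fix per day, screens for large spatial/temporal gaps, and writes the step
series consumed by `mmcp fit`.

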