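"""Parametric-bootstrap confidence intervals for the MMCP parameters.

Wald or profile-likelihood intervals are unavailable because the likelihood
contains the discontinuous migratory indicator, so uncertainty is obtained
by simulation: draw step series from the fitted model (exponential step
lengths, von Mises turning angles, the fitted change-points), preserving
the observed series' timestamps and validity masks, refit each replicate,
and take the 2.5% / 97.5% quantiles of the replicate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import MMCPFit, _active_params
from .search import SearchConfig, fit_mmcp
from .track import StepSeries, Track

__all__ = ["BootstrapResult", "simulate_from_fit", "bootstrap_cis", "reconstruct_track"]


@dataclass
class BootstrapResult:
    """Percentile confidence intervals from parametric-bootstrap refits.

    ``estimates`` holds one row per successful replicate; ``ci`` maps each
    parameter name to its (2.5%, 97.5%) quantiles.  Replicates with no
    feasible refit are counted in ``failures`` and excluded.  A result with
    more than 50% failures is flagged ``unreliable``.
    """

    n_paths: int
    estimates: pd.DataFrame
    ci: dict[str, tuple[float, float]]
    seed: int
    failures: int

    @property
    def unreliable(self) -> bool:
        return self.failures > self.n_paths / 2

    def to_dataframe(self, point: dict[str, float] | None = None) -> pd.DataFrame:
        rows = []
        for name, (lo, hi) in self.ci.items():
            row = {"parameter": name, "lower": lo, "upper": hi}
            if point is not None:
                row["estimate"] = point.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _param_names(c: int, shared_mig: bool) -> list[str]:
    names = [f"t{i + 1}" for i in range(2 * c)] + ["rho0"]
    n_mig = 1 if shared_mig else c
    names += [f"rho{i + 1}" for i in range(n_mig)]
    names += ["kappa0"] + [f"kappa{i + 1}" for i in range(n_mig)]
    return names


def _param_vector(fit: MMCPFit) -> dict[str, float]:
    p = fit.params
    vec = {f"t{i + 1}": float(v) for i, v in enumerate(p.t)}
    vec["rho0"] = p.rho0
    for i, v in enumerate(p.rho_mig):
        vec[f"rho{i + 1}"] = float(v)
    vec["kappa0"] = p.kappa0
    for i, v in enumerate(p.kappa_mig):
        vec[f"kappa{i + 1}"] = float(v)
    return vec


def simulate_from_fit(fit: MMCPFit, template: StepSeries, seed: int) -> StepSeries:
    """Draw a step series from a fitted model onto a template's skeleton.

    The template's times and validity masks are preserved ("same size and
    temporal extent", including the missingness pattern); at each valid
    entry ``r ~ Exponential(mean = rho0 + I rho_n)`` and
    ``phi ~ vonMises(0, kappa0 + I kappa_n)`` using the fitted indicator at
    that entry's time.
    """
    if fit.params is None:
        raise ValueError("cannot simulate from an infeasible fit")
    rng = np.random.default_rng(seed)
    rho, kap = _active_params(template.times, fit.params)
    n = len(template)
    r = np.full(n, np.nan)
    phi = np.full(n, np.nan)
    vr, vp = template.valid_r, template.valid_phi
    r[vr] = rng.exponential(rho[vr])
    phi[vp] = rng.vonmises(0.0, kap[vp])  # kappa = 0 is circular-uniform
    return StepSeries(template.times.copy(), r, phi, vr.copy(), vp.copy())


def reconstruct_track(steps: StepSeries, track_id: str = "simulated") -> Track:
    """Accumulate a planar track from a fully valid step series.

    Headings start at 0 and accumulate the turning angles; positions start
    at the origin.  Irrelevant to the likelihood (which sees only r, phi)
    but useful for plotting simulated paths.
    """
    heading = np.concatenate([[0.0], np.where(steps.valid_phi, np.nan_to_num(steps.phi), 0.0)]).cumsum()[1:]
    r = np.where(steps.valid_r, np.nan_to_num(steps.r), 0.0)
    x = np.concatenate([[0.0], np.cumsum(r * np.cos(heading))])
    y = np.concatenate([[0.0], np.cumsum(r * np.sin(heading))])
    t0 = steps.times[0] - (steps.times[1] - steps.times[0]) if len(steps) > 1 else steps.times[0] - 1
    times = np.concatenate([[t0], steps.times])
    return Track(id=track_id, times=times, x=x, y=y)


def bootstrap_cis(
    steps: StepSeries,
    fit: MMCPFit,
    n_paths: int = 100,
    config: SearchConfig | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """95% percentile CIs for all MMCP parameters by parametric bootstrap.

    Each of ``n_paths`` replicates simulates a series from ``fit`` onto the
    observed skeleton (sub-seed ``seed + i``) and refits with the same
    search configuration; CIs are the 2.5%/97.5% quantiles of the feasible
    refit estimates.
    """
    if fit.params is None:
        raise ValueError("cannot bootstrap an infeasible fit")
    config = config or SearchConfig()
    if config.bounds is None:
        # anchor replicate searches to the observed series' window
        config = SearchConfig(**{**config.__dict__, "bounds": config.resolved_bounds(steps)})
    c = fit.params.c
    names = _param_names(c, fit.params.shared_mig)
    rows = []
    failures = 0
    for i in range(n_paths):
        rep = simulate_from_fit(fit, steps, seed=seed + i)
        refit = fit_mmcp(rep, c=c, config=config)
        if refit.feasible:
            rows.append(_param_vector(refit))
        else:
            failures += 1
    estimates = pd.DataFrame(rows, columns=names)
    ci = {}
    for name in names:
        vals = estimates[name].to_numpy()
        if len(vals):
            ci[name] = (float(np.quantile(vals, 0.025)), float(np.quantile(vals, 0.975)))
        else:
            ci[name] = (np.nan, np.nan)
    return BootstrapResult(n_paths=n_paths, estimates=estimates, ci=ci, seed=seed, failures=failures)
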