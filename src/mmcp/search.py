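"""Multi-resolution grid search for the MMCP change-points.

The likelihood is discontinuous in the change-points, so they are found by
direct search: evaluate the profile NLL on a coarse ``(2c)``-dimensional
lattice (default resolution 14 sampling intervals), carry the ``top_k``
lowest-NLL tuples to successively finer lattices (7, 3, 1) restricted to
windows around each carried tuple, and return the best candidate seen
anywhere.  An exhaustive search over the finest lattice is provided as a
slow exact reference.

Candidate NLLs are computed in batch from prefix sums over the time-sorted
step series, so a search stage costs O(n + m) for m candidates rather than
O(n m).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .likelihood import (
    KAPPA_CAP,
    InfeasibleCandidate,
    MMCPFit,
    MMCPParams,
    log_i0,
    migratory_indicator,
    profile_mle,
    solve_kappa,
)
from .track import StepSeries

logger = logging.getLogger(__name__)

__all__ = ["SearchConfig", "enumerate_candidates", "fit_mmcp", "exhaustive_fit", "MMCPChangePoint"]

_EXHAUSTIVE_GUARD = 1_000_000


@dataclass
class SearchConfig:
    """Settings for the multi-resolution change-point search.

    ``grid_schedule`` lists strictly decreasing lattice resolutions in the
    track's time units (days for daily data), ending at the finest
    resolution searched.  ``min_duration`` is a strict lower bound on each
    migratory period's length ``t_{2n} - t_{2n-1}`` (7 days for hawk-style
    fits, 14 for caribou-style); ``min_gap`` bounds the separation between
    consecutive periods.  ``bounds`` is the feasible time window for
    change-points (defaults to the data's time span).
    """

    grid_schedule: tuple[float, ...] = (14.0, 7.0, 3.0, 1.0)
    top_k: int = 5
    min_duration: float = 7.0
    min_gap: float = 0.0
    bounds: tuple[float, float] | None = None
    min_segment: int = 2
    shared_mig: bool = False
    kappa_cap: float = KAPPA_CAP

    def __post_init__(self) -> None:
        gs = tuple(float(g) for g in self.grid_schedule)
        if len(gs) == 0 or any(g <= 0 for g in gs):
            raise ValueError("grid_schedule must hold positive resolutions")
        if any(b >= a for a, b in zip(gs, gs[1:])):
            raise ValueError("grid_schedule must be strictly decreasing")
        self.grid_schedule = gs
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")

    @property
    def g_min(self) -> float:
        return self.grid_schedule[-1]

    def resolved_bounds(self, steps: StepSeries) -> tuple[float, float]:
        if self.bounds is not None:
            return (float(self.bounds[0]), float(self.bounds[1]))
        return (float(steps.times.min()), float(steps.times.max()))


class _SeriesStats:
    """Prefix sums of the step series' sufficient statistics, time-sorted."""

    def __init__(self, steps: StepSeries):
        order = np.argsort(steps.times, kind="stable")
        self.times = steps.times[order]
        r = np.where(steps.valid_r, np.nan_to_num(steps.r), 0.0)[order]
        cos = np.where(steps.valid_phi, np.cos(np.nan_to_num(steps.phi)), 0.0)[order]
        vr = steps.valid_r[order].astype(float)
        vp = steps.valid_phi[order].astype(float)
        z = np.zeros(1)
        self.cum_nr = np.concatenate([z, np.cumsum(vr)])
        self.cum_sr = np.concatenate([z, np.cumsum(r)])
        self.cum_np = np.concatenate([z, np.cumsum(vp)])
        self.cum_sc = np.concatenate([z, np.cumsum(cos)])
        self.tot_nr = self.cum_nr[-1]
        self.tot_sr = self.cum_sr[-1]
        self.tot_np = self.cum_np[-1]
        self.tot_sc = self.cum_sc[-1]


def _pool_nll(n_r, sum_r, rho_act, n_phi, sum_cos, kap_act):
    return (
        n_r * np.log(rho_act)
        + sum_r / rho_act
        + n_phi * (np.log(2 * np.pi) + log_i0(kap_act))
        - kap_act * sum_cos
    )


def _evaluate_batch(stats: _SeriesStats, cands: np.ndarray, config: SearchConfig) -> np.ndarray:
    """Profile NLL for each candidate row of change-points.

    Infeasible candidates (a pool with fewer than ``min_segment`` valid step
    lengths or no valid turning angle) get ``+inf``.
    """
    m, k2 = cands.shape
    c = k2 // 2
    idx = np.searchsorted(stats.times, cands, side="right")  # (m, 2c)
    lo, hi = idx[:, 0::2], idx[:, 1::2]
    n_r = stats.cum_nr[hi] - stats.cum_nr[lo]  # (m, c) per migratory period
    s_r = stats.cum_sr[hi] - stats.cum_sr[lo]
    n_p = stats.cum_np[hi] - stats.cum_np[lo]
    s_c = stats.cum_sc[hi] - stats.cum_sc[lo]
    if config.shared_mig and c > 1:
        n_r = n_r.sum(axis=1, keepdims=True)
        s_r = s_r.sum(axis=1, keepdims=True)
        n_p = n_p.sum(axis=1, keepdims=True)
        s_c = s_c.sum(axis=1, keepdims=True)
    n_r0 = stats.tot_nr - n_r.sum(axis=1)
    s_r0 = stats.tot_sr - s_r.sum(axis=1)
    n_p0 = stats.tot_np - n_p.sum(axis=1)
    s_c0 = stats.tot_sc - s_c.sum(axis=1)

    feasible = (n_r0 >= config.min_segment) & (n_p0 >= 1)
    feasible &= np.all(n_r >= config.min_segment, axis=1) & np.all(n_p >= 1, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        rho0 = s_r0 / n_r0
        feasible &= rho0 > 0
        rho0 = np.where(feasible, rho0, 1.0)
        kap0 = solve_kappa(np.where(feasible, s_c0 / np.maximum(n_p0, 1), 0.0), cap=config.kappa_cap)
        nll = _pool_nll(n_r0, s_r0, rho0, n_p0, s_c0, kap0)
        for p in range(n_r.shape[1]):
            ok = feasible & (n_r[:, p] > 0)
            mean_r = np.where(ok, s_r[:, p] / np.maximum(n_r[:, p], 1), 1.0)
            rho_act = np.maximum(mean_r, rho0)  # rho0 + max(0, mean - rho0)
            kap_hat = solve_kappa(
                np.where(ok, s_c[:, p] / np.maximum(n_p[:, p], 1), 0.0), cap=config.kappa_cap
            )
            kap_act = np.maximum(kap_hat, kap0)
            nll += _pool_nll(n_r[:, p], s_r[:, p], rho_act, n_p[:, p], s_c[:, p], kap_act)
    return np.where(feasible, nll, np.inf)


def _feasible_mask(cands: np.ndarray, config: SearchConfig) -> np.ndarray:
    """Ordering, duration and gap constraints on candidate rows."""
    ok = np.all(np.diff(cands, axis=1) > 0, axis=1)
    dur = cands[:, 1::2] - cands[:, 0::2]
    ok &= np.all(dur > config.min_duration, axis=1)
    if cands.shape[1] > 2 and config.min_gap > 0:
        gaps = cands[:, 2::2] - cands[:, 1:-1:2]
        ok &= np.all(gaps >= config.min_gap, axis=1)
    return ok


def _lattice(bounds: tuple[float, float], g: float) -> np.ndarray:
    lo, hi = bounds
    n = int(math.floor((hi - lo) / g + 1e-9))
    return lo + g * np.arange(n + 1)


def enumerate_candidates(
    steps: StepSeries,
    c: int,
    g: float,
    config: SearchConfig,
    centers: np.ndarray | None = None,
    previous_g: float | None = None,
) -> np.ndarray:
    """Feasible change-point tuples on a lattice of resolution ``g``.

    Without ``centers``, the full ordered lattice over the config bounds is
    enumerated.  With ``centers`` (carried from a coarser stage of
    resolution ``previous_g``), the union of local lattices covering
    ``center +/- previous_g`` per coordinate is returned, deduplicated.
    Rows are in lexicographic order; every row satisfies the ordering,
    ``min_duration`` and ``min_gap`` constraints.
    """
    bounds = config.resolved_bounds(steps)
    if centers is None:
        values = _lattice(bounds, g)
        if c == 1:
            a, b = np.meshgrid(values, values, indexing="ij")
            cands = np.column_stack([a.ravel(), b.ravel()])
        else:
            cands = np.array(list(itertools.combinations(values, 2 * c)), dtype=float)
            if cands.size == 0:
                cands = cands.reshape(0, 2 * c)
    else:
        if previous_g is None:
            raise ValueError("previous_g required when refining around centers")
        half = int(math.ceil(previous_g / g))
        offsets = g * np.arange(-half, half + 1)
        pieces = []
        for center in np.atleast_2d(centers):
            axes = [np.clip(center[i] + offsets, bounds[0], bounds[1]) for i in range(2 * c)]
            grid = np.meshgrid(*axes, indexing="ij")
            pieces.append(np.column_stack([a.ravel() for a in grid]))
        cands = np.concatenate(pieces, axis=0)
        cands = np.unique(cands, axis=0)  # dedupe; unique sorts rows lexicographically
    cands = cands[_feasible_mask(cands, config)]
    return cands


def _run_search(
    steps: StepSeries, c: int, config: SearchConfig, exhaustive: bool
) -> MMCPFit:
    if steps.n_valid_r == 0 or steps.n_valid_phi == 0:
        return MMCPFit(None, np.inf, steps.n_valid_r, steps.n_valid_phi, feasible=False,
                       message="no valid step lengths or turning angles")
    stats = _SeriesStats(steps)
    best_nll = np.inf
    best_t: np.ndarray | None = None
    n_evaluated = 0

    def consider(cands: np.ndarray, nll: np.ndarray) -> None:
        nonlocal best_nll, best_t
        finite = np.isfinite(nll)
        if not finite.any():
            return
        i = int(np.argmin(nll))  # first occurrence: lexicographic tie-break
        if nll[i] < best_nll or (
            nll[i] == best_nll and best_t is not None and tuple(cands[i]) < tuple(best_t)
        ):
            best_nll = float(nll[i])
            best_t = cands[i].copy()

    if exhaustive:
        bounds = config.resolved_bounds(steps)
        n_values = len(_lattice(bounds, config.g_min))
        est = math.comb(n_values, 2 * c) if c > 1 else n_values * (n_values - 1) // 2
        if est > _EXHAUSTIVE_GUARD:
            raise ValueError(
                f"exhaustive search would evaluate ~{est} candidates "
                f"(> {_EXHAUSTIVE_GUARD}); use fit_mmcp or coarsen g_min"
            )
        cands = enumerate_candidates(steps, c, config.g_min, config)
        for start in range(0, len(cands), 200_000):
            chunk = cands[start : start + 200_000]
            consider(chunk, _evaluate_batch(stats, chunk, config))
        n_evaluated = len(cands)
    else:
        carried: np.ndarray | None = None
        prev_g: float | None = None
        for g in config.grid_schedule:
            cands = enumerate_candidates(steps, c, g, config, centers=carried, previous_g=prev_g)
            if len(cands) == 0:
                if carried is None:
                    break  # no feasible candidate at the coarsest stage
                prev_g = g
                continue
            nll = _evaluate_batch(stats, cands, config)
            n_evaluated += len(cands)
            consider(cands, nll)
            feasible_idx = np.flatnonzero(np.isfinite(nll))
            if len(feasible_idx) == 0:
                break
            order = feasible_idx[np.argsort(nll[feasible_idx], kind="stable")]
            carried = cands[order[: config.top_k]]
            prev_g = g
            logger.debug("grid g=%s: %d candidates, best NLL %.4f", g, len(cands), best_nll)

    if best_t is None:
        return MMCPFit(None, np.inf, steps.n_valid_r, steps.n_valid_phi, feasible=False,
                       message="no feasible change-point candidate; no migration estimable",
                       n_evaluated=n_evaluated)
    try:
        params = profile_mle(
            steps, best_t, c=c, shared_mig=config.shared_mig,
            min_segment=config.min_segment, kappa_cap=config.kappa_cap,
        )
    except InfeasibleCandidate:  # pragma: no cover - evaluator guarantees feasibility
        return MMCPFit(None, np.inf, steps.n_valid_r, steps.n_valid_phi, feasible=False,
                       message="winning candidate infeasible", n_evaluated=n_evaluated)
    return MMCPFit(params, best_nll, steps.n_valid_r, steps.n_valid_phi,
                   feasible=True, n_evaluated=n_evaluated)


def fit_mmcp(steps: StepSeries, c: int = 1, config: SearchConfig | None = None) -> MMCPFit:
    """Fit the MMCP model by multi-resolution grid search.

    Returns an infeasible :class:`MMCPFit` (``feasible=False``) rather than
    raising when no candidate satisfies the constraints.
    """
    return _run_search(steps, c, config or SearchConfig(), exhaustive=False)


def exhaustive_fit(steps: StepSeries, c: int = 1, config: SearchConfig | None = None) -> MMCPFit:
    """Exact minimiser over the complete finest lattice (slow reference).

    Refuses (with a size estimate) when the lattice would exceed 10^6
    candidate tuples.
    """
    return _run_search(steps, c, config or SearchConfig(), exhaustive=True)


class MMCPChangePoint(BaseEstimator):
    """Multi-metric change-point estimator of migration timing.

    Fits exponential step lengths and von Mises turning angles with ``c``
    migratory periods ``(t_{2n-1}, t_{2n}]`` during which the mean step
    length and angular concentration increase, locating the change-points by
    multi-resolution grid search over the profile negative log-likelihood.

    Parameters
    ----------
    c : int
        Number of migratory periods.
    grid_schedule : tuple of float
        Strictly decreasing lattice resolutions (in the series' time units).
    top_k : int
        Candidates carried from each stage to the next.
    min_duration : float
        Strict lower bound on each period's duration.
    min_gap : float
        Minimum separation between consecutive migratory periods.
    bounds : (float, float) or None
        Feasible change-point window; defaults to the data's time span.
    shared_mig : bool
        Share a single (rho_1, kappa_1) increment across all periods.
    min_segment : int
        Minimum valid step lengths per pool for a candidate to be feasible.
    exhaustive : bool
        Use the exact full-lattice search instead of the staged search.

    Attributes
    ----------
    fit_ : MMCPFit
        Full fit record.
    changepoints_ : ndarray
        Fitted change-points ``t_1 < ... < t_{2c}``.
    params_ : MMCPParams
    nll_, aic_ : float
    speed_ratio_ : ndarray
        Per-period R = (rho0 + rho_n)/rho0.
    feasible_ : bool

    Examples
    --------
    >>> from mmcp.simulate import speed_switch_spec, simulate_cvm_switch
    >>> from mmcp.track import compute_steps
    >>> lt = simulate_cvm_switch(speed_switch_spec(), seed=0)
    >>> est = MMCPChangePoint(c=1).fit(compute_steps(lt.track))
    >>> est.changepoints_  # doctest: +SKIP
    array([100., 200.])
    """

    def __init__(
        self,
        c: int = 1,
        grid_schedule: tuple[float, ...] = (14.0, 7.0, 3.0, 1.0),
        top_k: int = 5,
        min_duration: float = 7.0,
        min_gap: float = 0.0,
        bounds: tuple[float, float] | None = None,
        shared_mig: bool = False,
        min_segment: int = 2,
        kappa_cap: float = KAPPA_CAP,
        exhaustive: bool = False,
    ):
        self.c = c
        self.grid_schedule = grid_schedule
        self.top_k = top_k
        self.min_duration = min_duration
        self.min_gap = min_gap
        self.bounds = bounds
        self.shared_mig = shared_mig
        self.min_segment = min_segment
        self.kappa_cap = kappa_cap
        self.exhaustive = exhaustive

    def _config(self) -> SearchConfig:
        return SearchConfig(
            grid_schedule=tuple(self.grid_schedule),
            top_k=self.top_k,
            min_duration=self.min_duration,
            min_gap=self.min_gap,
            bounds=self.bounds,
            min_segment=self.min_segment,
            shared_mig=self.shared_mig,
            kappa_cap=self.kappa_cap,
        )

    def fit(self, X: StepSeries, y=None) -> "MMCPChangePoint":
        """Fit to a :class:`~mmcp.track.StepSeries`."""
        if not isinstance(X, StepSeries):
            raise TypeError("X must be a StepSeries (see mmcp.track.compute_steps)")
        fit = _run_search(X, self.c, self._config(), exhaustive=self.exhaustive)
        self.fit_ = fit
        self.feasible_ = fit.feasible
        self.nll_ = fit.nll
        self.n_evaluated_ = fit.n_evaluated
        if fit.feasible:
            self.params_ = fit.params
            self.changepoints_ = fit.params.t
            self.aic_ = fit.aic
            self.speed_ratio_ = fit.R
        else:
            self.params_ = None
            self.changepoints_ = None
            self.aic_ = np.inf
            self.speed_ratio_ = None
        return self

    def predict(self, times) -> np.ndarray:
        """Binary migratory labels at the given times (Eq.-1 indicator)."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("estimator is not fitted")
        times = np.asarray(times, dtype=float)
        if not self.feasible_:
            return np.zeros(times.shape, dtype=int)
        ind, _ = migratory_indicator(times, self.params_)
        return ind

    def score(self, X: StepSeries, y=None) -> float:
        """Mean log-likelihood per used term under the fitted parameters."""
        from .likelihood import total_nll

        if not self.feasible_:
            return -np.inf
        n = X.n_valid_r + X.n_valid_phi
        return -total_nll(X, self.params_) / max(n, 1)
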