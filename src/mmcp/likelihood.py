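"""The multi-metric change-point (MMCP) likelihood.

The model assumes exponential step lengths and von Mises turning angles
(mean direction fixed at zero).  Migration is a set of ``c`` half-open time
intervals ``(t_{2n-1}, t_{2n}]`` during which the mean step length rises
from ``rho_0`` to ``rho_0 + rho_n`` and the angular concentration from
``kappa_0`` to ``kappa_0 + kappa_n``.  The per-location negative
log-likelihood is::

    log(rho) + r_t / rho + log(2 pi I_0(kappa)) - kappa cos(phi_t)

with ``rho = rho_0 + I_mig(t) rho_n`` and ``kappa = kappa_0 +
I_mig(t) kappa_n``.  With the change-points fixed the likelihood separates,
so the rho and kappa maximum-likelihood estimates are profile MLEs: segment
means for rho, and the inverse of ``A(kappa) = I_1(kappa)/I_0(kappa)``
applied to the segment mean cosine for kappa; migratory increments are
truncated at zero (migration is hypothesised to be faster and straighter,
never slower).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .track import StepSeries

__all__ = [
    "MMCPParams",
    "MMCPFit",
    "KAPPA_CAP",
    "migratory_indicator",
    "point_nll",
    "total_nll",
    "profile_mle",
    "solve_kappa",
    "log_i0",
    "aic",
    "delta_aic",
    "n_parameters",
    "speed_ratio",
]

#: Upper bound for the von Mises concentration MLE.  The MLE diverges when
#: all angles coincide; 500 is far beyond any plausible animal track and is
#: numerically safe on the log scale.
KAPPA_CAP = 500.0


@dataclass
class MMCPParams:
    """Parameters of a ``c``-migration MMCP model.

    ``t`` holds the ordered change-points ``t_1 < ... < t_{2c}``;
    ``rho_mig`` / ``kappa_mig`` hold the per-period increments (length ``c``,
    or length 1 when ``shared_mig``).
    """

    t: np.ndarray
    rho0: float
    rho_mig: np.ndarray
    kappa0: float
    kappa_mig: np.ndarray
    shared_mig: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rho_mig = np.atleast_1d(np.asarray(self.rho_mig, dtype=float))
        self.kappa_mig = np.atleast_1d(np.asarray(self.kappa_mig, dtype=float))
        if self.t.ndim != 1 or len(self.t) % 2:
            raise ValueError("t must hold an even number of change-points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("change-points must be strictly increasing")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if np.any(self.rho_mig < 0) or np.any(self.kappa_mig < 0) or self.kappa0 < 0:
            raise ValueError("increments and kappa0 must be non-negative")
        n_mig = 1 if self.shared_mig else self.c
        if len(self.rho_mig) != n_mig or len(self.kappa_mig) != n_mig:
            raise ValueError("rho_mig/kappa_mig length must match c (or 1 if shared)")

    @property
    def c(self) -> int:
        return len(self.t) // 2

    def period_params(self, period: int) -> tuple[float, float]:
        """Active (rho, kappa) inside migratory period ``period`` (0-based)."""
        i = 0 if self.shared_mig else period
        return self.rho0 + self.rho_mig[i], self.kappa0 + self.kappa_mig[i]

    def to_dict(self) -> dict:
        return {
            "c": self.c,
            "t": self.t.tolist(),
            "rho0": self.rho0,
            "rho_mig": self.rho_mig.tolist(),
            "kappa0": self.kappa0,
            "kappa_mig": self.kappa_mig.tolist(),
            "shared_mig": self.shared_mig,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MMCPParams":
        return cls(
            t=np.asarray(d["t"], dtype=float),
            rho0=float(d["rho0"]),
            rho_mig=np.asarray(d["rho_mig"], dtype=float),
            kappa0=float(d["kappa0"]),
            kappa_mig=np.asarray(d["kappa_mig"], dtype=float),
            shared_mig=bool(d.get("shared_mig", False)),
        )


@dataclass
class MMCPFit:
    """A fitted MMCP model: parameters plus fit diagnostics."""

    params: MMCPParams | None
    nll: float
    n_r: int
    n_phi: int
    feasible: bool = True
    message: str = ""
    n_evaluated: int = 0

    @property
    def aic(self) -> float:
        return aic(self)

    @property
    def R(self) -> np.ndarray:
        """Per-period speed ratio (rho0 + rho_n) / rho0."""
        p = self.params
        return (p.rho0 + p.rho_mig) / p.rho0

    def to_dict(self) -> dict:
        d = {
            "nll": self.nll,
            "n_r": self.n_r,
            "n_phi": self.n_phi,
            "feasible": self.feasible,
            "message": self.message,
        }
        if self.params is not None:
            d.update(self.params.to_dict())
            d["aic"] = self.aic
            d["R"] = self.R.tolist()
        return d


def migratory_indicator(t, params: MMCPParams):
    """Evaluate the migratory indicator I_mig at time(s) ``t``.

    Returns ``(indicator, period)`` where ``indicator`` is 1 exactly on the
    half-open intervals ``(t_{2n-1}, t_{2n}]`` and ``period`` is the 0-based
    period index (-1 outside migration).
    """
    t = np.asarray(t, dtype=float)
    ind = np.zeros(t.shape, dtype=int)
    period = np.full(t.shape, -1, dtype=int)
    for n in range(params.c):
        inside = (t > params.t[2 * n]) & (t <= params.t[2 * n + 1])
        ind[inside] = 1
        period[inside] = n
    if t.ndim == 0:
        return int(ind), int(period)
    return ind, period


def log_i0(kappa):
    """log of the order-0 modified Bessel function, overflow-free."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(kappa)) + kappa


def point_nll(r, phi, active_rho: float, active_kappa: float) -> float:
    """Negative log-likelihood of one location's step metrics.

    Either ``r`` or ``phi`` may be None (masked); the corresponding term is
    omitted.  ``active_rho``/``active_kappa`` are the regime parameters at
    that location's time.
    """
    if active_rho <= 0 or active_kappa < 0:
        raise ValueError("need active_rho > 0 and active_kappa >= 0")
    nll = 0.0
    if r is not None:
        if not np.isfinite(r):
            raise ValueError("non-finite step length")
        nll += np.log(active_rho) + r / active_rho
    if phi is not None:
        if not np.isfinite(phi):
            raise ValueError("non-finite turning angle")
        nll += np.log(2 * np.pi) + log_i0(active_kappa) - active_kappa * np.cos(phi)
    return float(nll)


def _active_params(times: np.ndarray, params: MMCPParams) -> tuple[np.ndarray, np.ndarray]:
    ind, period = migratory_indicator(times, params)
    rho = np.full(times.shape, params.rho0)
    kap = np.full(times.shape, params.kappa0)
    for n in range(params.c):
        sel = period == n
        if sel.any():
            r_n, k_n = params.period_params(n)
            rho[sel] = r_n
            kap[sel] = k_n
    return rho, kap


def total_nll(steps: StepSeries, params: MMCPParams) -> float:
    """Total NLL of a step series under the model; masked terms contribute 0."""
    if steps.n_valid_r == 0:
        raise ValueError("need at least one valid step length")
    rho, kap = _active_params(steps.times, params)
    vr, vp = steps.valid_r, steps.valid_phi
    nll = np.sum(np.log(rho[vr]) + steps.r[vr] / rho[vr])
    nll += np.sum(np.log(2 * np.pi) + log_i0(kap[vp]) - kap[vp] * np.cos(steps.phi[vp]))
    return float(nll)


def _bessel_ratio(kappa):
    return special.i1e(kappa) / special.i0e(kappa)


def solve_kappa(mean_cos, cap: float = KAPPA_CAP):
    """Von Mises concentration MLE with mean direction fixed at 0.

    Solves ``I_1(kappa)/I_0(kappa) = mean_cos`` for ``kappa >= 0``
    (vectorised Newton iteration seeded with the Fisher approximation).
    Non-positive mean cosines give 0; solutions above ``cap`` are clamped.
    """
    m = np.asarray(mean_cos, dtype=float)
    scalar = m.ndim == 0
    m = np.atleast_1d(m)
    out = np.zeros(m.shape)
    pos = m > 0
    hi = pos & (m >= _bessel_ratio(cap))
    out[hi] = cap
    solve = pos & ~hi
    if solve.any():
        ms = m[solve]
        # Fisher (1993) piecewise start
        k = np.where(
            ms < 0.53,
            2 * ms + ms**3 + 5 * ms**5 / 6,
            np.where(ms < 0.85, -0.4 + 1.39 * ms + 0.43 / (1 - ms), 1.0 / (ms**3 - 4 * ms**2 + 3 * ms)),
        )
        k = np.clip(k, 1e-8, cap)
        for _ in range(40):
            a = _bessel_ratio(k)
            da = 1.0 - a / k - a * a  # d/dk [I1/I0]
            step = (a - ms) / da
            k_new = np.clip(k - step, 1e-12, cap)
            if np.max(np.abs(k_new - k)) < 1e-12:
                k = k_new
                break
            k = k_new
        out[solve] = k
    return float(out[0]) if scalar else out


@dataclass
class _Pools:
    """Per-pool sufficient statistics used by the profile MLEs."""

    n_r: np.ndarray
    sum_r: np.ndarray
    n_phi: np.ndarray
    sum_cos: np.ndarray


def _pool_stats(steps: StepSeries, t: np.ndarray, shared_mig: bool) -> _Pools:
    """Sufficient statistics for the non-migratory pool (index 0) and each
    migratory pool (indices 1..c, or a single pooled index 1 if shared)."""
    c = len(t) // 2
    dummy = MMCPParams(
        t=t, rho0=1.0, rho_mig=np.zeros(1 if shared_mig else c),
        kappa0=0.0, kappa_mig=np.zeros(1 if shared_mig else c), shared_mig=shared_mig,
    )
    ind, period = migratory_indicator(steps.times, dummy)
    pool = np.where(ind == 1, (1 if shared_mig else period + 1), 0)
    n_pools = 2 if shared_mig else c + 1
    n_r = np.zeros(n_pools)
    sum_r = np.zeros(n_pools)
    n_phi = np.zeros(n_pools)
    sum_cos = np.zeros(n_pools)
    vr, vp = steps.valid_r, steps.valid_phi
    np.add.at(n_r, pool[vr], 1)
    np.add.at(sum_r, pool[vr], steps.r[vr])
    np.add.at(n_phi, pool[vp], 1)
    np.add.at(sum_cos, pool[vp], np.cos(steps.phi[vp]))
    return _Pools(n_r, sum_r, n_phi, sum_cos)


class InfeasibleCandidate(Exception):
    """Raised when a change-point candidate leaves a pool too small to fit."""


def profile_mle(
    steps: StepSeries,
    t,
    c: int | None = None,
    shared_mig: bool = False,
    min_segment: int = 2,
    kappa_cap: float = KAPPA_CAP,
) -> MMCPParams:
    """Profile MLEs of (rho, kappa) at fixed change-points ``t``.

    rho0 is the mean non-migratory step length; kappa0 inverts
    ``I_1/I_0`` against the mean non-migratory cos(phi).  Each migratory
    period's increment is the period MLE minus the baseline, truncated at 0.
    Raises :class:`InfeasibleCandidate` when any pool has fewer than
    ``min_segment`` valid step lengths or no valid turning angle.
    """
    t = np.asarray(t, dtype=float)
    if c is not None and len(t) != 2 * c:
        raise ValueError("t must have length 2c")
    pools = _pool_stats(steps, t, shared_mig)
    if np.any(pools.n_r < min_segment) or np.any(pools.n_phi < 1):
        raise InfeasibleCandidate(f"pool too small at t={t.tolist()}")
    rho0 = pools.sum_r[0] / pools.n_r[0]
    if rho0 <= 0:
        raise InfeasibleCandidate("non-migratory mean step length is zero")
    kappa0 = solve_kappa(pools.sum_cos[0] / pools.n_phi[0], cap=kappa_cap)
    rho_mig = np.maximum(0.0, pools.sum_r[1:] / pools.n_r[1:] - rho0)
    kap_hat = solve_kappa(pools.sum_cos[1:] / pools.n_phi[1:], cap=kappa_cap)
    kappa_mig = np.maximum(0.0, np.atleast_1d(kap_hat) - kappa0)
    return MMCPParams(
        t=t, rho0=float(rho0), rho_mig=rho_mig, kappa0=float(kappa0),
        kappa_mig=kappa_mig, shared_mig=shared_mig,
    )


def n_parameters(c: int, shared_mig: bool = False) -> int:
    """Parameter count k for AIC: 2c change-points + baseline (rho0, kappa0)
    + per-period increments (2c, or 2 if shared)."""
    return 2 * c + 2 + (2 if shared_mig else 2 * c)


def aic(fit: MMCPFit) -> float:
    """Akaike Information Criterion, 2k + 2 NLL."""
    if fit.params is None:
        raise ValueError("cannot compute AIC of an infeasible fit")
    k = n_parameters(fit.params.c, fit.params.shared_mig)
    return 2 * k + 2 * fit.nll


def delta_aic(fit_a: MMCPFit, fit_b: MMCPFit) -> float:
    """AIC(fit_a) - AIC(fit_b), valid only for fits on the same term set."""
    if (fit_a.n_r, fit_a.n_phi) != (fit_b.n_r, fit_b.n_phi):
        raise ValueError("fits use different likelihood term sets; AIC not comparable")
    return aic(fit_a) - aic(fit_b)


def speed_ratio(params: MMCPParams, period: int = 0) -> float:
    """R = (rho0 + rho_period) / rho0, the migratory speed-up factor."""
    i = 0 if params.shared_mig else period
    return float((params.rho0 + params.rho_mig[i]) / params.rho0)
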