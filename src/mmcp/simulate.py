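"""Generative movement simulators for validating the change-point model.

Three processes, each producing a 300-step path whose middle third
(times in ``(100, 200]``) is migratory:

* **speed switch** — correlated velocity movement (CVM) whose mean speed nu
  rises from 1 to 5 during migration (autocorrelation timescale tau = 2
  throughout);
* **timescale switch** — CVM with constant nu = 1 whose timescale tau rises
  from 2 to 20, straightening the path while leaving the marginal speed
  distribution unchanged;
* **bias switch** — discrete biased correlated random walk (BCRW) whose
  attraction point jumps from (0, 0) to (50, 0) and attraction strength
  from 0.5 to 0.9, with step-length (Weibull(1, 1)) and turning
  (kappa = 0.5) distributions unchanged.

The CVM is realised as a 2D Ornstein-Uhlenbeck velocity process with
per-axis stationary standard deviation ``sigma = nu * sqrt(2/pi)``, so the
stationary mean speed is nu (the speed is Rayleigh(sigma)); velocities use
the exact OU transition on substeps of ``dt_internal`` and positions come
from trapezoidal integration of the velocity.

A degradation model mimics real telemetry: each location is dropped
independently with probability 1/12 (the first is always kept so the path
stays anchored) and surviving coordinates are jittered with i.i.d. Gaussian
noise of per-axis variance sigma_e (0, 1 or 25 spatial units squared).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .track import Track

__all__ = [
    "CVMSpec",
    "BCRWSpec",
    "DegradationSpec",
    "LabeledTrack",
    "speed_switch_spec",
    "timescale_switch_spec",
    "bias_switch_spec",
    "simulate_cvm_switch",
    "simulate_bcrw_switch",
    "degrade_track",
]


@dataclass
class CVMSpec:
    """Correlated-velocity-movement simulation with phase switches.

    ``nu_schedule`` / ``tau_schedule`` give the mean speed and velocity
    autocorrelation timescale for the pre-migration, migration and
    post-migration phases; the phases change at ``switch_times``.
    """

    nu_schedule: tuple[float, float, float] = (1.0, 5.0, 1.0)
    tau_schedule: tuple[float, float, float] = (2.0, 2.0, 2.0)
    switch_times: tuple[float, float] = (100.0, 200.0)
    T: int = 300
    dt_out: float = 1.0
    dt_internal: float = 0.1

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.nu_schedule) or any(v <= 0 for v in self.tau_schedule):
            raise ValueError("nu and tau must be positive")
        if self.dt_internal > self.dt_out:
            raise ValueError("dt_internal must not exceed dt_out")
        t1, t2 = self.switch_times
        if not (0 < t1 < t2 < self.T * self.dt_out):
            raise ValueError("switch times must lie strictly inside (0, T * dt_out)")


@dataclass
class BCRWSpec:
    """Biased correlated random walk with an attraction-point switch.

    Step lengths are Weibull(``alpha`` shape, ``beta`` scale); headings mix
    the previous heading with the bearing to the phase's attraction point
    with weight ``A`` and receive von Mises noise of concentration
    ``kappa_turn``.
    """

    alpha: float = 1.0
    beta: float = 1.0
    kappa_turn: float = 0.5
    attraction_schedule: tuple[tuple[float, float], ...] = ((0.0, 0.0), (50.0, 0.0), (50.0, 0.0))
    A_schedule: tuple[float, float, float] = (0.5, 0.9, 0.5)
    switch_times: tuple[float, float] = (100.0, 200.0)
    T: int = 300

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.kappa_turn < 0:
            raise ValueError("need alpha, beta > 0 and kappa_turn >= 0")
        if any(not 0 <= a <= 1 for a in self.A_schedule):
            raise ValueError("attraction strengths must lie in [0, 1]")
        t1, t2 = self.switch_times
        if not (0 < t1 < t2 < self.T):
            raise ValueError("switch times must satisfy 0 < t1 < t2 < T")


@dataclass
class DegradationSpec:
    """Telemetry degradation: random dropout plus Gaussian jitter.

    ``sigma_e`` is the per-axis jitter *variance* (the simulation study uses
    0, 1 and 25 spatial units squared).
    """

    p_miss: float = 1.0 / 12.0
    sigma_e: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_miss < 1:
            raise ValueError("p_miss must lie in [0, 1)")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")


@dataclass
class LabeledTrack:
    """A simulated track with its per-location true behavioural state.

    ``velocity`` carries the instantaneous (vx, vy) at each location for
    continuous-time generators (None for discrete walks); the marginal speed
    ``hypot(vx, vy)`` is the quantity the timescale-switch model holds
    constant across phases.
    """

    track: Track
    labels: np.ndarray  # 1 = migratory, aligned with track locations
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.track):
            raise ValueError("labels must align 1:1 with locations")
        if self.velocity is not None and len(self.velocity) != len(self.track):
            raise ValueError("velocity must align 1:1 with locations")

    @property
    def speed(self) -> np.ndarray | None:
        return None if self.velocity is None else np.hypot(self.velocity[:, 0], self.velocity[:, 1])


def speed_switch_spec(**overrides) -> CVMSpec:
    """The simulation study's speed-switch schedule: nu 1 -> 5 -> 1, tau = 2."""
    return CVMSpec(**({"nu_schedule": (1.0, 5.0, 1.0), "tau_schedule": (2.0, 2.0, 2.0)} | overrides))


def timescale_switch_spec(**overrides) -> CVMSpec:
    """The timescale-switch schedule: nu = 1, tau 2 -> 20 -> 2."""
    return CVMSpec(**({"nu_schedule": (1.0, 1.0, 1.0), "tau_schedule": (2.0, 20.0, 2.0)} | overrides))


def bias_switch_spec(**overrides) -> BCRWSpec:
    """The bias-switch schedule: attraction (0,0) -> (50,0), A 0.5 -> 0.9 -> 0.5."""
    return BCRWSpec(**overrides)


def _phase_of(times: np.ndarray, switch_times: tuple[float, float]) -> np.ndarray:
    """Phase index (0/1/2) governing the dynamics arriving at each time.

    A location at time t was reached under migration dynamics exactly when
    ``switch_1 < t <= switch_2``, matching the model's half-open indicator.
    """
    t1, t2 = switch_times
    return np.where(times <= t1, 0, np.where(times <= t2, 1, 2)).astype(int)


def _labels_for(times: np.ndarray, switch_times: tuple[float, float]) -> np.ndarray:
    t1, t2 = switch_times
    return ((times > t1) & (times <= t2)).astype(int)


def simulate_cvm_switch(spec: CVMSpec, seed: int, track_id: str = "cvm") -> LabeledTrack:
    """Simulate a CVM path with phase switches in (nu, tau).

    The OU velocity uses exact transitions per ``dt_internal`` substep; at a
    nu-switch the current velocity is rescaled by the ratio of stationary
    standard deviations (direction preserved, no boundary transient); at a
    pure tau-switch it is carried unchanged.
    """
    rng = np.random.default_rng(seed)
    n_sub = round(spec.dt_out / spec.dt_internal)
    sub_times = spec.dt_internal * np.arange(1, spec.T * n_sub + 1)
    phases = _phase_of(sub_times, spec.switch_times)
    sigmas = np.array(spec.nu_schedule) * np.sqrt(2.0 / np.pi)
    taus = np.array(spec.tau_schedule)

    v = rng.normal(0.0, sigmas[0], size=2)  # stationary start
    pos = np.zeros(2)
    out_xy = np.zeros((spec.T + 1, 2))
    out_v = np.zeros((spec.T + 1, 2))
    out_v[0] = v
    prev_phase = 0
    h = spec.dt_internal
    noise = rng.normal(size=(len(sub_times), 2))
    for i, ph in enumerate(phases):
        if ph != prev_phase:
            if sigmas[ph] != sigmas[prev_phase]:
                v = v * (sigmas[ph] / sigmas[prev_phase])
            prev_phase = ph
        tau = taus[ph]
        decay = np.exp(-h / tau)
        sd = sigmas[ph] * np.sqrt(1.0 - decay**2)
        v_new = v * decay + sd * noise[i]
        pos = pos + 0.5 * (v + v_new) * h  # trapezoidal integration
        v = v_new
        if (i + 1) % n_sub == 0:
            out_xy[(i + 1) // n_sub] = pos
            out_v[(i + 1) // n_sub] = v

    times = spec.dt_out * np.arange(spec.T + 1)
    track = Track(id=track_id, times=times, x=out_xy[:, 0], y=out_xy[:, 1], dt_nominal=spec.dt_out)
    return LabeledTrack(track, _labels_for(times, spec.switch_times), velocity=out_v)


def simulate_bcrw_switch(spec: BCRWSpec, seed: int, track_id: str = "bcrw") -> LabeledTrack:
    """Simulate a biased correlated random walk with an attraction switch.

    The expected heading at each step is the direction of
    ``A * u(bearing-to-attraction) + (1 - A) * u(previous heading)`` with
    ``u`` the unit vector; the realised heading adds von Mises noise.  The
    first heading is uniform.
    """
    rng = np.random.default_rng(seed)
    arrive = np.arange(1.0, spec.T + 1)
    phases = _phase_of(arrive, spec.switch_times)
    attraction = np.array(spec.attraction_schedule, dtype=float)
    A = np.array(spec.A_schedule, dtype=float)

    xy = np.zeros((spec.T + 1, 2))
    heading = rng.uniform(-np.pi, np.pi)
    steps = spec.beta * rng.weibull(spec.alpha, size=spec.T)
    for i in range(spec.T):
        ph = phases[i]
        if i > 0:
            target = attraction[ph] - xy[i]
            dist = np.hypot(*target)
            bearing = np.arctan2(target[1], target[0]) if dist > 0 else heading
            vec = A[ph] * np.array([np.cos(bearing), np.sin(bearing)]) + (1 - A[ph]) * np.array(
                [np.cos(heading), np.sin(heading)]
            )
            mu = np.arctan2(vec[1], vec[0]) if np.hypot(*vec) > 0 else heading
            heading = (
                rng.vonmises(mu, spec.kappa_turn) if spec.kappa_turn > 0 else rng.uniform(-np.pi, np.pi)
            )
        # i == 0: the first heading is the uniform draw itself
        xy[i + 1] = xy[i] + steps[i] * np.array([np.cos(heading), np.sin(heading)])

    times = np.arange(spec.T + 1, dtype=float)
    track = Track(id=track_id, times=times, x=xy[:, 0], y=xy[:, 1], dt_nominal=1.0)
    return LabeledTrack(track, _labels_for(times, spec.switch_times))


def degrade_track(labeled: LabeledTrack, spec: DegradationSpec, seed: int) -> LabeledTrack:
    """Apply random dropout and coordinate jitter to a simulated track.

    Each location after the first is removed independently with probability
    ``p_miss``; surviving coordinates get i.i.d. Gaussian noise of per-axis
    variance ``sigma_e``.  Labels follow retained locations.
    """
    rng = np.random.default_rng(seed)
    n = len(labeled.track)
    keep = rng.random(n) >= spec.p_miss
    keep[0] = True  # anchor the path
    idx = np.flatnonzero(keep)
    track = labeled.track.take(idx)
    if spec.sigma_e > 0:
        sd = np.sqrt(spec.sigma_e)
        track = replace(
            track,
            x=track.x + rng.normal(0.0, sd, size=len(idx)),
            y=track.y + rng.normal(0.0, sd, size=len(idx)),
        )
    vel = None if labeled.velocity is None else labeled.velocity[idx]
    return LabeledTrack(track, labeled.labels[idx], velocity=vel)
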