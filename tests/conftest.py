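import numpy as np
import pytest

from mmcp.likelihood import MMCPFit, MMCPParams
from mmcp.bootstrap import simulate_from_fit
from mmcp.track import StepSeries, Track


def full_template(T: int, t0: float = 1.0) -> StepSeries:
    """A fully observed step-series skeleton with arrival times t0..t0+T-1."""
    times = t0 + np.arange(float(T))
    valid_r = np.ones(T, dtype=bool)
    valid_phi = np.ones(T, dtype=bool)
    valid_phi[0] = False  # the first step has no previous heading
    return StepSeries(times, np.ones(T), np.zeros(T), valid_r, valid_phi)


def mmcp_series(
    t=(100.0, 200.0),
    rho0: float = 1.0,
    rho1: float = 4.0,
    kappa0: float = 0.5,
    kappa1: float = 2.0,
    T: int = 300,
    seed: int = 0,
) -> StepSeries:
    """Draw a complete step series from known MMCP parameters."""
    params = MMCPParams(t=np.asarray(t, float), rho0=rho0, rho_mig=[rho1],
                        kappa0=kappa0, kappa_mig=[kappa1])
    fit = MMCPFit(params, 0.0, T, T - 1)
    return simulate_from_fit(fit, full_template(T), seed=seed)


def piecewise_series(seed: int = 0) -> StepSeries:
    """Noiseless piecewise step lengths: r = 1 (times 1-50), 10 (51-80), 1 (81-120)."""
    T = 120
    times = np.arange(1.0, T + 1)
    r = np.where((times > 50) & (times <= 80), 10.0, 1.0)
    rng = np.random.default_rng(seed)
    phi = rng.normal(0.0, 0.1, size=T)
    valid_r = np.ones(T, dtype=bool)
    valid_phi = np.ones(T, dtype=bool)
    valid_phi[0] = False
    return StepSeries(times, r, phi, valid_r, valid_phi)


def straight_track(n: int = 10, dt: float = 1.0) -> Track:
    times = dt * np.arange(n)
    return Track(id="straight", times=times, x=np.arange(float(n)), y=np.zeros(n), dt_nominal=dt)


@pytest.fixture(scope="session")
def speed_switch_steps():
    """One undegraded speed-switch CVM path converted to a step series."""
    from mmcp.simulate import simulate_cvm_switch, speed_switch_spec
    from mmcp.track import compute_steps

    return compute_steps(simulate_cvm_switch(speed_switch_spec(), seed=42).track)
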