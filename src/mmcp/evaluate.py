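"""Replicate-level evaluation of fitted migrations.

Two tools: classification profiles over simulation replicates (the fraction
of replicates labelled migratory at each timestep, plus change-point error
summaries), and a Gaussian closed-form Bhattacharyya affinity between the
non-migratory ranges of a two-migration fit, used to judge whether those
ranges are spatially disjoint as true migration would imply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import MMCPFit, migratory_indicator
from .track import Track

__all__ = [
    "ClassificationProfile",
    "RangeOverlap",
    "classify_timesteps",
    "build_profile",
    "segment_ranges",
    "gaussian_bhattacharyya",
]


@dataclass
class ClassificationProfile:
    """Per-timestep migratory fractions across replicate fits."""

    times: np.ndarray
    prop_migratory: np.ndarray
    n_reps: int
    model_tag: str = ""
    errors: pd.DataFrame | None = None  # per-replicate t-hat errors vs truth

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "prop_migratory": self.prop_migratory})


@dataclass
class RangeOverlap:
    """Bhattacharyya affinity between two non-migratory range estimates."""

    pair: tuple[int, int]
    ba: float
    defined: bool = True


def classify_timesteps(fit: MMCPFit, times) -> np.ndarray:
    """Binary migratory labels on an evaluation grid (0s if infeasible)."""
    times = np.asarray(times, dtype=float)
    if fit.params is None:
        return np.zeros(times.shape, dtype=int)
    ind, _ = migratory_indicator(times, fit.params)
    return ind


def build_profile(
    fits: list[MMCPFit],
    times,
    true_changepoints: tuple[float, float] | None = (100.0, 200.0),
    model_tag: str = "",
) -> ClassificationProfile:
    """Pointwise mean of per-fit migratory labels across replicates.

    When ``true_changepoints`` is given, also tabulates per-replicate
    ``(t_hat_1 - t_1, t_hat_2 - t_2)`` errors with their median and median
    absolute deviation (robust to the occasional wild fit).
    """
    times = np.asarray(times, dtype=float)
    labels = np.stack([classify_timesteps(f, times) for f in fits])
    prop = labels.mean(axis=0)
    errors = None
    if true_changepoints is not None:
        t1, t2 = true_changepoints
        rows = []
        for i, f in enumerate(fits):
            if f.params is not None and f.params.c >= 1:
                rows.append({"replicate": i, "t1_err": f.params.t[0] - t1, "t2_err": f.params.t[1] - t2})
            else:
                rows.append({"replicate": i, "t1_err": np.nan, "t2_err": np.nan})
        errors = pd.DataFrame(rows)
        errors.attrs["median"] = errors[["t1_err", "t2_err"]].median().to_dict()
        mad = (errors[["t1_err", "t2_err"]] - errors[["t1_err", "t2_err"]].median()).abs().median()
        errors.attrs["mad"] = mad.to_dict()
    return ClassificationProfile(times, prop, n_reps=len(fits), model_tag=model_tag, errors=errors)


def segment_ranges(track: Track, fit: MMCPFit) -> list[np.ndarray]:
    """Index sets of the non-migratory ranges of a two-migration fit.

    For change-points ``t1 < t2 < t3 < t4``: locations with ``t <= t1``,
    with ``t2 < t <= t3``, and with ``t > t4`` (the model's half-open
    boundary convention, so a location exactly at ``t1`` is non-migratory
    and one exactly at ``t2`` migratory).  An empty segment triggers a
    warning.
    """
    if fit.params is None or fit.params.c != 2:
        raise ValueError("segment_ranges requires a feasible c = 2 fit")
    ind, _ = migratory_indicator(track.times, fit.params)
    t = fit.params.t
    segments = [
        np.flatnonzero(track.times <= t[0]),
        np.flatnonzero((track.times > t[1]) & (track.times <= t[2])),
        np.flatnonzero(track.times > t[3]),
    ]
    for i, seg in enumerate(segments):
        if len(seg) == 0:
            warnings.warn(f"non-migratory segment {i} is empty", stacklevel=2)
    # consistency: these are exactly the non-migratory locations
    assert sum(len(s) for s in segments) == int((ind == 0).sum())
    return segments


def gaussian_bhattacharyya(seg_a: np.ndarray, seg_b: np.ndarray, pair=(0, 1)) -> RangeOverlap:
    """Closed-form Bhattacharyya affinity between two Gaussian range fits.

    Fits a bivariate Gaussian (sample mean and covariance) to each
    segment's locations and returns ``BA = exp(-D_B)`` with::

        D_B = (1/8)(mu_a - mu_b)' Sbar^-1 (mu_a - mu_b)
              + (1/2) ln( det Sbar / sqrt(det S_a det S_b) ),
        Sbar = (S_a + S_b) / 2.

    Segments need at least 3 non-collinear locations; degenerate
    (singular-covariance) segments yield an undefined, flagged result.
    """
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("segments must be (n, 2) coordinate arrays")
    if len(a) < 3 or len(b) < 3:
        return RangeOverlap(pair=pair, ba=np.nan, defined=False)
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    s_a = np.cov(a, rowvar=False)
    s_b = np.cov(b, rowvar=False)
    sbar = 0.5 * (s_a + s_b)
    det_a, det_b, det_bar = np.linalg.det(s_a), np.linalg.det(s_b), np.linalg.det(sbar)
    if det_a <= 0 or det_b <= 0 or det_bar <= 0:
        return RangeOverlap(pair=pair, ba=np.nan, defined=False)
    d = mu_a - mu_b
    db = 0.125 * d @ np.linalg.solve(sbar, d) + 0.5 * np.log(det_bar / np.sqrt(det_a * det_b))
    return RangeOverlap(pair=pair, ba=float(np.exp(-db)), defined=True)
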