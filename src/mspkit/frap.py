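"""FRAP recovery kinetics: normalization, exponential fitting, summaries.

Fluorescence recovery after photobleaching of a nuclear region is
summarized by a single-exponential model

    I(t) = plateau - (plateau - floor) * exp(-k * t),  t > 0,

where ``floor`` is the post-bleach intensity, ``plateau`` the recovered
level and ``k`` the exchange rate; the half-maximal recovery time is
``t_half = ln(2)/k``. Traces are normalized to the pre-bleach intensity
(the t=0 point, which anchors the normalization and is excluded from the
fit). Experiments are fitted individually and half-times averaged across
experiments — the average of per-experiment fits, not a fit of the
averaged curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "FrapFitError",
    "FrapFit",
    "HalftimeSummary",
    "ExponentialRecoveryModel",
    "normalize_trace",
    "fit_exponential",
    "fit_traces",
    "average_halftime",
    "compartment_ratio",
]

K_BOUNDS = (1e-5, 10.0)


class FrapFitError(RuntimeError):
    """Raised when a recovery fit cannot converge (e.g. constant trace)."""


@dataclass
class FrapFit:
    """A converged single-exponential recovery fit."""

    k: float
    plateau: float
    floor: float
    t_half: float
    rms: float
    converged: bool
    trace_id: str = ""
    compartment: str = ""

    def to_dict(self) -> dict:
        return {
            "trace_id": self.trace_id,
            "compartment": self.compartment,
            "k_per_s": self.k,
            "plateau": self.plateau,
            "floor": self.floor,
            "t_half_s": self.t_half,
            "rms": self.rms,
            "converged": self.converged,
        }


@dataclass
class HalftimeSummary:
    mean_t_half: float
    sem: float
    n: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_t_half_s": self.mean_t_half,
            "sem_s": self.sem,
            "n": self.n,
            "n_excluded": self.n_excluded,
        }


def normalize_trace(
    time_s: np.ndarray, raw_intensity: np.ndarray, pre_bleach_value: float
) -> pd.DataFrame:
    """Divide a raw intensity series by the pre-bleach reference.

    No clipping is applied; the t=0 point equals 1 exactly when the raw
    series starts at the reference value.
    """
    if pre_bleach_value <= 0:
        raise ValueError("pre_bleach_value must be > 0")
    t = np.asarray(time_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return pd.DataFrame(
        {"time_s": t, "intensity": np.asarray(raw_intensity, dtype=float) / pre_bleach_value}
    )


def _recovery(t: np.ndarray, k: float, plateau: float, floor: float) -> np.ndarray:
    return plateau - (plateau - floor) * np.exp(-k * t)


class ExponentialRecoveryModel(BaseEstimator):
    """Least-squares single-exponential FRAP fit with free floor and plateau.

    Initialization follows the trace: the floor guess is the first
    post-bleach intensity, the plateau guess the mean of the last 10% of
    points, and the rate guess comes from the time at which the trace
    first crosses half of (plateau - floor). The rate is bounded to
    ``k in (1e-5, 10) 1/s``; floor and plateau are free, so the fit is
    invariant to uniform rescaling of the intensities.

    Attributes (after ``fit``): ``k_``, ``plateau_``, ``floor_``,
    ``t_half_``, ``rms_``, ``converged_``.
    """

    def __init__(self, exclude_t0: bool = True):
        self.exclude_t0 = exclude_t0

    def fit(self, time_s, intensity=None) -> "ExponentialRecoveryModel":
        if intensity is None and isinstance(time_s, pd.DataFrame):
            t = time_s["time_s"].to_numpy(dtype=float)
            y = time_s["intensity"].to_numpy(dtype=float)
        else:
            t = np.asarray(time_s, dtype=float)
            y = np.asarray(intensity, dtype=float)
        if self.exclude_t0:
            mask = t > 0
            t, y = t[mask], y[mask]
        if t.size < 5:
            raise ValueError("need at least 5 post-bleach points")
        if np.ptp(y) == 0:
            raise FrapFitError("constant trace: recovery rate is undefined")

        floor0 = float(y[0])
        tail = max(1, int(round(0.1 * y.size)))
        plateau0 = float(np.mean(y[-tail:]))
        if plateau0 <= floor0:
            plateau0 = float(np.max(y))
            if plateau0 <= floor0:
                raise FrapFitError("no recovery above the post-bleach floor")
        half_level = floor0 + 0.5 * (plateau0 - floor0)
        above = np.nonzero(y >= half_level)[0]
        t_half0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
        k0 = min(max(math.log(2.0) / max(t_half0, t[0]), K_BOUNDS[0] * 10), K_BOUNDS[1] * 0.1)

        try:
            popt, _ = curve_fit(
                _recovery,
                t,
                y,
                p0=(k0, plateau0, floor0),
                bounds=([K_BOUNDS[0], -np.inf, -np.inf], [K_BOUNDS[1], np.inf, np.inf]),
                maxfev=10_000,
            )
        except RuntimeError as exc:
            raise FrapFitError(f"exponential fit did not converge: {exc}") from exc
        k, plateau, floor = map(float, popt)
        if k <= 0:
            raise FrapFitError(f"non-physical recovery rate k={k}")
        self.k_ = k
        self.plateau_ = plateau
        self.floor_ = floor
        self.t_half_ = math.log(2.0) / k
        self.rms_ = float(np.sqrt(np.mean((y - _recovery(t, *popt)) ** 2)))
        self.converged_ = True
        return self

    def predict(self, time_s) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        return _recovery(t, self.k_, self.plateau_, self.floor_)


def fit_exponential(trace: pd.DataFrame) -> FrapFit:
    """Fit one normalized trace; raises :class:`FrapFitError` on failure."""
    model = ExponentialRecoveryModel().fit(trace)
    tid = str(trace["trace_id"].iloc[0]) if "trace_id" in trace.columns else ""
    comp = str(trace["compartment"].iloc[0]) if "compartment" in trace.columns else ""
    return FrapFit(
        model.k_, model.plateau_, model.floor_, model.t_half_, model.rms_,
        True, tid, comp,
    )


def fit_traces(traces: pd.DataFrame) -> tuple[list[FrapFit], list[str]]:
    """Fit every trace in a long-format table, collecting failures.

    Returns ``(fits, failed_trace_ids)``; failed traces are excluded from
    averages but reported, never silently dropped.
    """
    fits: list[FrapFit] = []
    failed: list[str] = []
    for tid, sub in traces.groupby("trace_id", sort=False):
        try:
            fits.append(fit_exponential(sub))
        except (FrapFitError, ValueError):
            failed.append(str(tid))
    return fits, failed


def average_halftime(fits: list[FrapFit], n_excluded: int = 0) -> HalftimeSummary:
    """Arithmetic mean and SEM of per-experiment half-times."""
    if not fits:
        raise ValueError("no converged fits to average")
    th = np.array([f.t_half for f in fits])
    sem = float(th.std(ddof=1) / math.sqrt(th.size)) if th.size > 1 else float("nan")
    return HalftimeSummary(float(th.mean()), sem, int(th.size), n_excluded)


def compartment_ratio(foci_fits: list[FrapFit], other_fits: list[FrapFit]) -> float:
    """Ratio of mean half-times, foci over the other compartment (>1 = slower foci)."""
    if not foci_fits or not other_fits:
        raise ValueError("both fit lists must be non-empty")
    return average_halftime(foci_fits).mean_t_half / average_halftime(other_fits).mean_t_half
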