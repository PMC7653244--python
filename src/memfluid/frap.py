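"""FRAP (fluorescence recovery after photobleaching) quantification.

A circular membrane region is bleached and the refill of fluorescence by
diffusing labeled lipids is followed over time.  The acquisition protocol
assumed here records a small number of pre-bleach frames, a discrete bleach
event, and a regular post-bleach series (default: 2 pre-bleach frames, then
50 frames at 2 s intervals).

Double normalization maps the raw trace to [0, 1]:

1. optional constant or per-frame background subtraction,
2. optional acquisition-bleach correction against a whole-cell reference
   ROI, ``F(t) * R_pre / R(t)``,
3. floor/pre-bleach scaling ``N(t) = (F(t) - F_bleach) / (F_pre - F_bleach)``
   with ``F_pre`` the mean of the pre-bleach frames and ``F_bleach`` the
   first post-bleach frame.

The *recovery rate* at a report time is ``100 * N(t)`` at the nearest frame
(endpoint convention), and a single-exponential model

    N(t) = A * (1 - exp(-t * ln 2 / t_half))

fitted over the post-bleach frames yields the mobile fraction ``A`` and
half-time ``t_half``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FRAPSeries",
    "FRAPResult",
    "FitResult",
    "normalize",
    "recovery_rate",
    "fit_recovery",
    "DegenerateTraceError",
    "FitError",
]

LN2 = float(np.log(2.0))


class DegenerateTraceError(ValueError):
    """Pre-bleach and bleach-floor intensities coincide; nothing to normalize."""


class FitError(RuntimeError):
    """Single-exponential recovery fit failed; message carries diagnostics."""


@dataclass
class FRAPSeries:
    """Time-stamped bleached-ROI intensity trace.

    ``times`` are seconds on the acquisition clock (strictly increasing);
    the first ``n_pre`` frames are pre-bleach, and frame ``n_pre`` (the
    ``bleach_index``) is the first post-bleach frame.  ``reference`` is an
    optional whole-cell trace for acquisition-bleach correction and
    ``background`` an optional constant or per-frame trace.
    """

    times: np.ndarray
    intensity: np.ndarray
    n_pre: int = 2
    reference: np.ndarray | None = None
    background: "float | np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape or self.times.ndim != 1:
            raise ValueError("times and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.n_pre < len(self.times)):
            raise ValueError("n_pre must leave at least one post-bleach frame")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.intensity.shape:
                raise ValueError("reference trace length must match intensity")
        if self.intensity[self.n_pre] >= self.intensity[: self.n_pre].mean():
            raise ValueError(
                "no bleach detected: first post-bleach frame is not below "
                "the pre-bleach mean"
            )

    @property
    def bleach_index(self) -> int:
        return self.n_pre

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_pre: int = 2) -> "FRAPSeries":
        """Build from columns time_s, roi_intensity and the optional
        reference_intensity / background_intensity columns."""
        ref = df["reference_intensity"].to_numpy() if "reference_intensity" in df else None
        bg = df["background_intensity"].to_numpy() if "background_intensity" in df else None
        return cls(
            times=df["time_s"].to_numpy(),
            intensity=df["roi_intensity"].to_numpy(),
            n_pre=n_pre,
            reference=ref,
            background=bg,
        )

    @classmethod
    def from_csv(cls, path: "str | Path", n_pre: int = 2) -> "FRAPSeries":
        return cls.from_dataframe(pd.read_csv(path), n_pre=n_pre)


@dataclass
class FRAPResult:
    """Normalized recovery trace plus derived quantities.

    ``normalized`` spans the whole acquisition (pre-bleach mean exactly 1,
    bleach frame exactly 0); ``post_times`` place t = 0 at the first
    post-bleach frame.  ``recovery_rate_pct`` / ``report_time`` and the fit
    fields are filled in by :func:`recovery_rate` and :func:`fit_recovery`.
    """

    times: np.ndarray
    normalized: np.ndarray
    n_pre: int
    recovery_rate_pct: float | None = None
    report_time: float | None = None
    mobile_fraction: float | None = None
    half_time: float | None = None
    fit_rmse: float | None = None

    @property
    def bleach_index(self) -> int:
        return self.n_pre

    @property
    def post_times(self) -> np.ndarray:
        """Post-bleach times with origin at the first post-bleach frame."""
        return self.times[self.n_pre :] - self.times[self.n_pre]

    @property
    def post_normalized(self) -> np.ndarray:
        return self.normalized[self.n_pre :]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "normalized": self.normalized})


def normalize(series: FRAPSeries) -> FRAPResult:
    """Double-normalize a FRAP trace (see module docs).

    Raises :class:`DegenerateTraceError` when the pre-bleach level equals the
    bleach floor.
    """
    f = series.intensity.astype(float).copy()
    if series.background is not None:
        f = f - np.asarray(series.background, dtype=float)
    if series.reference is not None:
        r = series.reference.astype(float).copy()
        if series.background is not None:
            r = r - np.asarray(series.background, dtype=float)
        if np.any(r <= 0):
            raise ValueError("reference trace must stay positive after background subtraction")
        r_pre = r[: series.n_pre].mean()
        f = f * (r_pre / r)
    f_pre = f[: series.n_pre].mean()
    f_bleach = f[series.bleach_index]
    if f_pre == f_bleach:
        raise DegenerateTraceError("pre-bleach level equals bleach floor")
    n = (f - f_bleach) / (f_pre - f_bleach)
    return FRAPResult(times=series.times.copy(), normalized=n, n_pre=series.n_pre)


def recovery_rate(result: FRAPResult, report_time: float | None = None) -> float:
    """Recovery rate (%) at the post-bleach frame nearest ``report_time``.

    ``report_time`` is seconds after the first post-bleach frame; the default
    is the last frame.  The frame actually used is stored on the result as
    ``report_time``.
    """
    post_t = result.post_times
    if report_time is None:
        report_time = float(post_t[-1])
    if report_time < 0:
        raise ValueError("report_time precedes the bleach event")
    idx = int(np.argmin(np.abs(post_t - report_time)))
    pct = 100.0 * float(result.post_normalized[idx])
    result.recovery_rate_pct = pct
    result.report_time = float(post_t[idx])
    return pct


@dataclass
class FitResult:
    """Single-exponential recovery fit: plateau (mobile fraction), half-time."""

    mobile_fraction: float
    half_time: float
    fit_rmse: float
    half_time_identifiable: bool = True


def _model(t, a, t_half):
    return a * (1.0 - np.exp(-t * LN2 / t_half))


def fit_recovery(result: FRAPResult) -> FitResult:
    """Least-squares fit of ``N(t) = A (1 - 2^(-t / t_half))`` to the
    post-bleach frames.

    ``A`` is constrained to [0, 1.05] (small overshoot tolerated).  With a
    flat trace (A ~ 0) the half-time is unidentifiable and flagged.  Fit
    failure raises :class:`FitError` with diagnostics, never silently.
    """
    t = result.post_times
    y = result.post_normalized
    if len(t) < 10:
        raise ValueError(f"need >= 10 post-bleach frames, got {len(t)}")

    a0 = float(np.clip(np.mean(y[-5:]), 0.01, 1.05))
    above = np.flatnonzero(y >= a0 / 2.0)
    t0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1] / 4.0)
    try:
        popt, _ = curve_fit(
            _model,
            t,
            y,
            p0=(a0, max(t0, 1e-6)),
            bounds=([0.0, 1e-9], [1.05, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError(
            f"recovery fit failed: {exc}; p0=({a0:.3g}, {t0:.3g}), "
            f"n={len(t)}, y_range=({y.min():.3g}, {y.max():.3g})"
        ) from exc
    a_hat, t_half = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((_model(t, *popt) - y) ** 2)))
    fit = FitResult(
        mobile_fraction=a_hat,
        half_time=t_half,
        fit_rmse=rmse,
        half_time_identifiable=a_hat >= 0.01,
    )
    result.mobile_fraction = a_hat
    result.half_time = t_half
    result.fit_rmse = rmse
    return fit
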