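"""Laurdan emission-spectrum analysis for liposome experiments.

Spectra are sampled on a wavelength grid (default 400–550 nm, excitation
390 nm).  The module locates emission peaks with sub-grid precision, splits
the spectrum into the blue (400–460 nm) and red (470–530 nm) Laurdan bands
(the 460–470 nm gap belongs to neither), and flags red shifts of the peak —
the characteristic signature of increased membrane fluidity or lipid damage
is a shift of roughly 50 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "EmissionSpectrum",
    "SpectrumPeak",
    "RedShift",
    "find_peak",
    "detect_red_shift",
    "band_intensities",
    "loading_curve",
    "NoPeakError",
    "BandCoverageError",
    "BLUE_BAND",
    "RED_BAND",
]

BLUE_BAND = (400.0, 460.0)
RED_BAND = (470.0, 530.0)


class NoPeakError(ValueError):
    """Spectrum is flat; no emission peak exists."""


class BandCoverageError(ValueError):
    """Wavelength grid does not cover a requested integration band."""


@dataclass
class EmissionSpectrum:
    """Sampled fluorescence emission intensities over a wavelength grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1-D arrays")
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensities < 0) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite and non-negative")

    @classmethod
    def from_csv(
        cls, path: "str | Path", intensity_column: str | None = None, label: str = ""
    ) -> "EmissionSpectrum":
        """Read columns ``wavelength_nm`` plus one intensity column."""
        df = pd.read_csv(path)
        if intensity_column is None:
            candidates = [c for c in df.columns if c != "wavelength_nm"]
            intensity_column = candidates[0]
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(),
            intensities=df[intensity_column].to_numpy(),
            label=label or intensity_column,
        )


@dataclass
class SpectrumPeak:
    """Emission peak location/height; ``smoothed`` marks pre-smoothing."""

    wavelength: float
    intensity: float
    smoothed: bool = False


@dataclass
class RedShift:
    shift_nm: float
    is_shifted: bool
    threshold_nm: float


def find_peak(spectrum: EmissionSpectrum, smooth_window: int = 5) -> SpectrumPeak:
    """Locate the emission peak with sub-grid precision.

    Intensities are moving-average smoothed (``smooth_window`` points,
    nearest-edge padding) and the maximum refined by parabolic interpolation
    through the three samples around the argmax.  Exact ties break toward
    the shorter wavelength.  A flat spectrum raises :class:`NoPeakError`.
    """
    wl = spectrum.wavelengths
    if wl.size < smooth_window:
        raise ValueError(
            f"need at least smooth_window={smooth_window} samples, got {wl.size}"
        )
    if smooth_window > 1:
        y = uniform_filter1d(spectrum.intensities, size=smooth_window, mode="nearest")
    else:
        y = spectrum.intensities.astype(float)
    if np.ptp(y) == 0:
        raise NoPeakError("flat spectrum has no peak")

    idx = int(np.flatnonzero(y == y.max())[0])  # first max = shortest wavelength
    peak_wl = float(wl[idx])
    peak_int = float(y[idx])
    if 0 < idx < len(y) - 1:
        y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # genuine local curvature; vertex of the parabola
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                # assumes a locally uniform grid around the maximum
                step = 0.5 * (wl[idx + 1] - wl[idx - 1])
                peak_wl = float(wl[idx] + delta * step)
                peak_int = float(y1 - 0.25 * (y0 - y2) * delta)
    return SpectrumPeak(wavelength=peak_wl, intensity=peak_int, smoothed=smooth_window > 1)


def detect_red_shift(
    reference: SpectrumPeak, test: SpectrumPeak, threshold: float = 50.0
) -> RedShift:
    """Shift of the test peak relative to the reference peak.

    Flags a red shift when the displacement toward longer wavelengths
    reaches ``threshold`` nm (default 50 nm, the characteristic Laurdan
    fluidity shift).
    """
    shift = float(test.wavelength - reference.wavelength)
    return RedShift(shift_nm=shift, is_shifted=shift >= threshold, threshold_nm=threshold)


def _band_integral(spectrum: EmissionSpectrum, band: tuple[float, float]) -> float:
    lo, hi = band
    wl, y = spectrum.wavelengths, spectrum.intensities
    if wl[0] > lo or wl[-1] < hi:
        raise BandCoverageError(
            f"grid [{wl[0]}, {wl[-1]}] nm does not cover band [{lo}, {hi}] nm"
        )
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, y)], y[inside], [np.interp(hi, wl, y)]))
    return float(np.trapezoid(ys, xs))


def band_intensities(spectrum: EmissionSpectrum) -> tuple[float, float]:
    """Trapezoidal band integrals (I_blue over 400–460 nm, I_red over
    470–530 nm), e.g. for cuvette-mode polarization via
    :func:`memfluid.laurdan_gp.polarization`."""
    return _band_integral(spectrum, BLUE_BAND), _band_integral(spectrum, RED_BAND)


def loading_curve(times, peaks) -> pd.DataFrame:
    """Tabulate peak intensity/wavelength over a timecourse.

    ``times`` (hours) and ``peaks`` (:class:`SpectrumPeak`) must have equal
    length >= 2.  The returned frame carries strict-monotonicity flags in
    ``df.attrs['intensity_monotone']`` / ``df.attrs['wavelength_monotone']``.
    """
    times = list(times)
    peaks = list(peaks)
    if len(times) != len(peaks) or len(times) < 2:
        raise ValueError("need matching times/peaks with at least 2 timepoints")
    df = pd.DataFrame(
        {
            "time_h": [float(t) for t in times],
            "peak_intensity": [p.intensity for p in peaks],
            "peak_wavelength_nm": [p.wavelength for p in peaks],
        }
    ).sort_values("time_h", ignore_index=True)
    df.attrs["intensity_monotone"] = bool(np.all(np.diff(df["peak_intensity"]) > 0))
    df.attrs["wavelength_monotone"] = bool(np.all(np.diff(df["peak_wavelength_nm"]) > 0))
    return df
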