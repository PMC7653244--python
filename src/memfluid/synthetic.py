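"""Seeded synthetic-data generators with known ground truth.

Every analysis stage of the package has a matching generator here, so the
whole pipeline is testable without external acquisitions:

* two-channel Laurdan image pairs with a prescribed true GP (Poisson photon
  noise by default),
* single-exponential FRAP recovery traces under the standard protocol
  (2 pre-bleach frames, 3 s bleach, 50 post-bleach frames at 2 s),
* Gaussian emission spectra on a 400–550 nm grid,
* four-component annexin/PI event mixtures with log-normal channel
  intensities.

Identical seed + parameters reproduce byte-identical output.
"""

from __future__ import annotations

import numpy as np

from memfluid.apoptosis import EventTable
from memfluid.frap import FRAPSeries
from memfluid.laurdan_gp import ImagePair
from memfluid.spectra import EmissionSpectrum

__all__ = [
    "gen_gp_image_pair",
    "gen_frap_series",
    "gen_spectrum",
    "gen_events",
    "DEFAULT_CHANNEL_PARAMS",
    "default_gate_thresholds",
]


def gen_gp_image_pair(
    gp_true,
    mean_total_intensity: float = 200.0,
    noise: str = "poisson",
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    gaussian_sd: float = 5.0,
) -> ImagePair:
    """Generate a registered blue/red Laurdan image pair.

    The noiseless per-pixel expectation satisfies
    ``(I_blue - I_red) / (I_blue + I_red) = gp_true`` and
    ``I_blue + I_red = mean_total_intensity``.  ``gp_true`` may be a scalar
    or a per-pixel field in [-1, 1].  ``noise`` is ``"none"``, ``"poisson"``
    (photon counting) or ``"gaussian"`` (additive, sd ``gaussian_sd``,
    clipped at 0).
    """
    if len(shape) != 2 or min(shape) < 4:
        raise ValueError("shape must be 2-D with dimensions >= 4 px")
    if mean_total_intensity <= 0:
        raise ValueError("mean_total_intensity must be positive")
    gp = np.broadcast_to(np.asarray(gp_true, dtype=float), shape)
    if np.any(gp < -1) or np.any(gp > 1):
        raise ValueError("gp_true must lie in [-1, 1]")

    mean_blue = mean_total_intensity * (1.0 + gp) / 2.0
    mean_red = mean_total_intensity * (1.0 - gp) / 2.0
    rng = np.random.default_rng(seed)
    if noise == "none":
        blue, red = mean_blue.copy(), mean_red.copy()
    elif noise == "poisson":
        blue = rng.poisson(mean_blue).astype(float)
        red = rng.poisson(mean_red).astype(float)
    elif noise == "gaussian":
        blue = np.clip(mean_blue + rng.normal(0.0, gaussian_sd, shape), 0.0, None)
        red = np.clip(mean_red + rng.normal(0.0, gaussian_sd, shape), 0.0, None)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return ImagePair(blue=blue, red=red)


def gen_frap_series(
    mobile_fraction: float,
    half_time: float,
    pre_frames: int = 2,
    post_frames: int = 50,
    frame_interval: float = 2.0,
    bleach_depth: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
    pre_level: float = 100.0,
    bleach_duration: float = 3.0,
) -> FRAPSeries:
    """Generate a FRAP intensity trace with single-exponential recovery.

    The noiseless normalized recovery is
    ``N(t) = mobile_fraction * (1 - 2^(-t / half_time))`` with t = 0 at the
    first post-bleach frame; pre-bleach frames sit at ``pre_level`` and the
    first post-bleach frame at the bleach floor
    ``pre_level * (1 - bleach_depth)``.  ``noise_sd`` is additive Gaussian
    noise in a.u. (default 1% of the pre-bleach level).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if half_time <= 0:
        raise ValueError("half_time must be positive")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must lie in (0, 1]")
    if pre_frames < 1 or post_frames < 2:
        raise ValueError("need >= 1 pre-bleach and >= 2 post-bleach frames")

    post_t = np.arange(post_frames) * frame_interval
    pre_t = -bleach_duration - frame_interval * np.arange(pre_frames - 1, -1, -1) - (
        0.0
    )
    times = np.concatenate([pre_t, post_t])
    floor = pre_level * (1.0 - bleach_depth)
    recovery = mobile_fraction * (1.0 - np.exp(-post_t * np.log(2.0) / half_time))
    intensity = np.concatenate(
        [np.full(pre_frames, pre_level), floor + (pre_level - floor) * recovery]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
    return FRAPSeries(times=times, intensity=intensity, n_pre=pre_frames)


def gen_spectrum(
    peak_wavelength: float = 450.0,
    peak_intensity: float = 100.0,
    fwhm: float = 40.0,
    grid: tuple[float, float, float] = (400.0, 550.0, 0.5),
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> EmissionSpectrum:
    """Generate a Gaussian emission spectrum on a wavelength grid.

    ``grid`` is ``(start_nm, stop_nm, step_nm)`` (stop inclusive).  Additive
    Gaussian noise is clipped at zero to keep intensities physical.
    """
    start, stop, step = grid
    if stop <= start or step <= 0:
        raise ValueError("grid must satisfy start < stop with positive step")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    wl = np.arange(start, stop + step / 2.0, step)
    if not (wl[0] <= peak_wavelength <= wl[-1]):
        raise ValueError("peak_wavelength must lie within the grid")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = peak_intensity * np.exp(-0.5 * ((wl - peak_wavelength) / sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, y.shape), 0.0, None)
    return EmissionSpectrum(wavelengths=wl, intensities=y, label=label)


#: Log-normal channel model: negative populations sit at median 30 a.u.,
#: positive at median 300 a.u., both with sigma 0.4 on the log scale — a
#: decade of separation typical of compensated FITC/PI cytometry exports.
DEFAULT_CHANNEL_PARAMS = {
    "negative_median": 30.0,
    "positive_median": 300.0,
    "sigma": 0.4,
}


def default_gate_thresholds(channel_params=None) -> tuple[float, float]:
    """Geometric-midpoint gate between the negative and positive medians."""
    p = channel_params or DEFAULT_CHANNEL_PARAMS
    th = float(np.sqrt(p["negative_median"] * p["positive_median"]))
    return th, th


def gen_events(
    n_events: int = 10_000,
    fractions: tuple[float, float, float, float] = (0.478, 0.270, 0.250, 0.002),
    channel_params: dict | None = None,
    seed: int = 0,
) -> EventTable:
    """Generate an annexin/PI event table from a four-component mixture.

    ``fractions`` are (live, early, late, necrotic) occupancy probabilities
    summing to 1.  Annexin is positive for early/late events, PI for
    late/necrotic; channel intensities are log-normal per
    ``DEFAULT_CHANNEL_PARAMS``.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (4,):
        raise ValueError("fractions must be (live, early, late, necrotic)")
    if np.any(frac < 0):
        raise ValueError("fractions must be non-negative")
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {frac.sum()!r}")
    p = channel_params or DEFAULT_CHANNEL_PARAMS
    rng = np.random.default_rng(seed)
    component = rng.choice(4, size=n_events, p=frac)  # 0 live,1 early,2 late,3 necrotic
    annexin_pos = (component == 1) | (component == 2)
    pi_pos = (component == 2) | (component == 3)

    def channel(positive: np.ndarray) -> np.ndarray:
        median = np.where(positive, p["positive_median"], p["negative_median"])
        return median * np.exp(rng.normal(0.0, p["sigma"], n_events))

    return EventTable(annexin=channel(annexin_pos), pi=channel(pi_pos))
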