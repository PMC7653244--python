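"""Generalized polarization (GP) analysis of two-channel Laurdan images.

Laurdan's emission spectrum shifts with the phase of the surrounding
phospholipids, so the ratio of a blue emission band (400–460 nm) to a red
band (470–530 nm) reports membrane fluidity.  The per-area polarization is

    P = (I_blue - I_red) / (I_blue + I_red)

and the GP of a measured area is the mean polarization over non-overlapping
4x4-pixel tiles, each tile contributing the polarization of its mean
intensities.  GP ranges from -1 to +1; lower GP means a more fluid membrane.
Because GP is a ratio it is independent of the local dye concentration.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from memfluid._stats import welch_table

__all__ = [
    "ImagePair",
    "GPResult",
    "polarization",
    "compute_gp",
    "gp_pseudocolor",
    "pseudocolor_to_polarization",
    "compare_gp",
]

HISTOGRAM_BINS = 100


class EmptyResultError(ValueError):
    """Raised when every tile of an image pair is excluded."""


@dataclass
class ImagePair:
    """Registered two-channel Laurdan intensity images.

    ``blue`` holds the 400–460 nm emission channel, ``red`` the 470–530 nm
    channel.  Both are 2-D arrays of the same shape with finite, non-negative
    intensities (arbitrary units); pixel coordinates are 0-based, row-major.
    """

    blue: np.ndarray
    red: np.ndarray

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.blue.ndim != 2 or self.red.ndim != 2:
            raise ValueError("channels must be 2-D arrays")
        if self.blue.shape != self.red.shape:
            raise ValueError(
                f"channel shapes differ: {self.blue.shape} vs {self.red.shape}"
            )
        for name, arr in (("blue", self.blue), ("red", self.red)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} channel contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} channel contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    @property
    def total(self) -> np.ndarray:
        """Summed-channel intensity image."""
        return self.blue + self.red


@dataclass
class GPResult:
    """GP scalar plus the tile-level polarization map it was averaged from.

    ``tile_polarizations`` covers the tile grid; excluded tiles (below the
    intensity floor, or zero denominator) are NaN.  ``histogram`` is a
    ``(bin_edges, densities)`` pair over the included tile polarizations,
    normalized to integrate to 1.
    """

    gp: float
    tile_polarizations: np.ndarray
    tile_size: int
    n_tiles_used: int
    n_tiles_excluded: int
    histogram: tuple[np.ndarray, np.ndarray]
    background: tuple[float, float] = (0.0, 0.0)

    def tile_table(self) -> pd.DataFrame:
        """Tidy per-tile table (tile row/col, polarization, included flag)."""
        rows, cols = np.indices(self.tile_polarizations.shape)
        vals = self.tile_polarizations
        return pd.DataFrame(
            {
                "tile_row": rows.ravel(),
                "tile_col": cols.ravel(),
                "polarization": vals.ravel(),
                "included": np.isfinite(vals).ravel(),
            }
        )


def polarization(i_blue, i_red):
    """Polarization ``(I_blue - I_red) / (I_blue + I_red)``.

    Accepts scalars or arrays of non-negative intensities.  A zero summed
    intensity is undefined: scalars raise ``ValueError`` (array entries
    become NaN so callers can exclude them).
    """
    b = np.asarray(i_blue, dtype=float)
    r = np.asarray(i_red, dtype=float)
    if np.any(b < 0) or np.any(r < 0):
        raise ValueError("intensities must be non-negative")
    total = b + r
    scalar = np.isscalar(i_blue) and np.isscalar(i_red)
    if scalar:
        if total == 0:
            raise ValueError("polarization undefined for zero total intensity")
        return float((b - r) / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (b - r) / np.where(total > 0, total, 1.0), np.nan)
    return out


def _auto_background(pair: ImagePair) -> tuple[float, float]:
    """Per-channel background from the dimmest 1% of summed-channel pixels.

    Images that contain no background region (synthetic full-field images,
    confluent fields of view) would otherwise have their signal subtracted
    away, so the estimate is discarded when the dimmest-1% mean exceeds half
    the median summed intensity.
    """
    total = pair.total.ravel()
    k = max(1, int(0.01 * total.size))
    order = np.argsort(total, kind="stable")[:k]
    bg_blue = float(pair.blue.ravel()[order].mean())
    bg_red = float(pair.red.ravel()[order].mean())
    if bg_blue + bg_red > 0.5 * float(np.median(total)):
        return 0.0, 0.0
    return bg_blue, bg_red


def _tile_means(arr: np.ndarray, tile_size: int) -> np.ndarray:
    ny, nx = arr.shape[0] // tile_size, arr.shape[1] // tile_size
    cropped = arr[: ny * tile_size, : nx * tile_size]
    return cropped.reshape(ny, tile_size, nx, tile_size).mean(axis=(1, 3))


def compute_gp(
    pair: ImagePair,
    tile_size: int = 4,
    background: float | str = "auto",
    min_tile_intensity: float | None = None,
) -> GPResult:
    """Tile an image pair and compute its GP.

    The image is split into non-overlapping ``tile_size`` x ``tile_size``
    blocks anchored at pixel (0, 0); partial edge tiles are dropped.  Each
    tile contributes the polarization of its background-subtracted mean
    channel intensities, and GP is the unweighted mean over included tiles.
    Tiles whose mean summed intensity falls below ``min_tile_intensity``
    (default: twice the summed background) or whose denominator vanishes are
    excluded and recorded as NaN.

    ``background`` is either a per-channel constant (a.u.) or ``"auto"``
    (estimate from the dimmest 1% of summed pixels; see module docs).
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if min(pair.shape) < tile_size:
        raise ValueError(
            f"image {pair.shape} smaller than tile_size {tile_size}"
        )
    if background == "auto":
        bg_blue, bg_red = _auto_background(pair)
    else:
        bg_blue = bg_red = float(background)
        if bg_blue < 0:
            raise ValueError("background must be non-negative")

    mean_blue = _tile_means(pair.blue, tile_size)
    mean_red = _tile_means(pair.red, tile_size)
    raw_total = mean_blue + mean_red

    if min_tile_intensity is None:
        min_tile_intensity = 2.0 * (bg_blue + bg_red)

    # Background subtraction clamps at zero: intensities cannot be negative.
    sub_blue = np.maximum(mean_blue - bg_blue, 0.0)
    sub_red = np.maximum(mean_red - bg_red, 0.0)
    denom = sub_blue + sub_red

    included = (raw_total >= min_tile_intensity) & (denom > 0)
    tiles = np.full(mean_blue.shape, np.nan)
    tiles[included] = (sub_blue[included] - sub_red[included]) / denom[included]

    n_used = int(included.sum())
    if n_used == 0:
        raise EmptyResultError("all tiles excluded (sub-background or zero denominator)")

    values = tiles[included]
    densities, edges = np.histogram(
        values, bins=HISTOGRAM_BINS, range=(-1.0, 1.0), density=True
    )
    return GPResult(
        gp=float(values.mean()),
        tile_polarizations=tiles,
        tile_size=tile_size,
        n_tiles_used=n_used,
        n_tiles_excluded=int(tiles.size - n_used),
        histogram=(edges, densities),
        background=(bg_blue, bg_red),
    )


def gp_pseudocolor(result: GPResult, cmap: str = "jet", bad_color=(0.0, 0.0, 0.0, 1.0)):
    """Render the tile polarization map as an RGBA image on a fixed [-1, 1] scale.

    Excluded tiles are drawn in ``bad_color``.  Returns an array of shape
    ``(n_tile_rows, n_tile_cols, 4)`` with values in [0, 1].
    """
    import matplotlib
    import matplotlib.colors as mcolors

    colormap = matplotlib.colormaps[cmap].copy()
    colormap.set_bad(bad_color)
    norm = mcolors.Normalize(vmin=-1.0, vmax=1.0)
    masked = np.ma.masked_invalid(result.tile_polarizations)
    return colormap(norm(masked))


def pseudocolor_to_polarization(rgba: np.ndarray, cmap: str = "jet", levels: int = 256):
    """Invert a :func:`gp_pseudocolor` rendering back to polarization values.

    Nearest-color lookup against ``levels`` samples of the colormap; accurate
    to the colormap quantization.  Cells matching no sample closely (e.g. the
    null color of excluded tiles) come back as NaN.
    """
    import matplotlib

    colormap = matplotlib.colormaps[cmap]
    samples = np.linspace(-1.0, 1.0, levels)
    table = colormap((samples + 1.0) / 2.0)[:, :3]
    flat = np.asarray(rgba)[..., :3].reshape(-1, 3)
    d2 = ((flat[:, None, :] - table[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    vals = samples[idx]
    vals[d2[np.arange(len(idx)), idx] > 1e-3] = np.nan
    return vals.reshape(np.asarray(rgba).shape[:-1])


def compare_gp(
    groups: Mapping[str, Sequence["GPResult | float"]],
    control: str,
) -> pd.DataFrame:
    """Summarize GP replicate groups: mean, SD, n, Welch p-value vs control."""
    numeric = {
        name: [g.gp if isinstance(g, GPResult) else float(g) for g in vals]
        for name, vals in groups.items()
    }
    return welch_table(numeric, control)
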