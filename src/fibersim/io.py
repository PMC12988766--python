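"""Raster I/O and physical pixel calibration.

Two-channel multiphoton acquisitions are carried as :class:`ImagePair`
objects: page 1 of a multi-page TIFF is the elastin (TPEF) channel and
page 2 the collagen (SHG) channel by default.  Pixel size in μm/px is
propagated from the TIFF resolution tags and travels with every derived
map so that downstream distance and thickness computations are in
physical units.

Coordinate convention: row-major arrays, origin at the top-left pixel,
0-based indices.  Orientation angles are measured from the image x-axis
(columns), counter-clockwise with the y-axis pointing up, in [0, 180)
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "IntensityImage",
    "ImagePair",
    "FeatureMap",
    "read_image_pair",
    "write_image_pair",
    "write_feature_map",
    "read_feature_map",
    "export_histogram",
]

CHANNELS = ("elastin", "collagen")

#: TIFF resolution unit code for centimeters.
_RESUNIT_CM = 3


@dataclass
class IntensityImage:
    """A single channel's 2-D non-negative intensity grid.

    Parameters
    ----------
    values
        2-D float array of intensities.
    pixel_size
        Physical pixel pitch in μm/px (square pixels).
    channel
        ``"elastin"`` or ``"collagen"``.
    """

    values: np.ndarray
    pixel_size: float
    channel: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity grid must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("intensity grid contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ImagePair:
    """An (elastin, collagen) channel pair on a common grid."""

    elastin: IntensityImage
    collagen: IntensityImage

    def __post_init__(self) -> None:
        if self.elastin.channel != "elastin" or self.collagen.channel != "collagen":
            raise ValueError("channels mislabelled")
        if self.elastin.shape != self.collagen.shape:
            raise ValueError("channel dimensions differ")
        if not np.isclose(self.elastin.pixel_size, self.collagen.pixel_size):
            raise ValueError("channel pixel sizes differ")

    @property
    def pixel_size(self) -> float:
        return self.elastin.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.elastin.shape


@dataclass
class FeatureMap:
    """A pixel-wise morphological feature map defined on fiber pixels.

    Values off the fiber mask are the NaN sentinel.  ``vrange`` is the
    declared valid range used for range checks and as fixed color limits
    when rendering.
    """

    name: str
    values: np.ndarray
    pixel_size: float
    vrange: tuple[float, float]
    channel: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("feature map must be a 1-D vector or 2-D grid")
        defined = self.values[np.isfinite(self.values)]
        lo, hi = self.vrange
        if defined.size and (defined.min() < lo - 1e-9 or defined.max() > hi + 1e-9):
            raise ValueError(
                f"{self.name} values [{defined.min():g}, {defined.max():g}] "
                f"outside declared range [{lo:g}, {hi:g}]"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid of pixels where the feature is defined."""
        return np.isfinite(self.values)

    @property
    def defined(self) -> np.ndarray:
        """1-D array of the defined (on-mask) values."""
        return self.values[self.mask]


class MissingChannelError(ValueError):
    """Raised when a file does not provide both spectral channels."""


def _resolution_tag(pixel_size_um: float) -> tuple[tuple[int, int], tuple[int, int]]:
    # TIFF stores pixels per resolution unit as a rational; encode with a
    # fixed fine denominator so the round trip keeps ~9 digits.
    px_per_cm = 1e4 / pixel_size_um
    rational = (int(round(px_per_cm * 1e4)), 10_000)
    return rational, rational


def _pixel_size_from_tags(page: tifffile.TiffPage) -> float | None:
    try:
        unit = page.tags["ResolutionUnit"].value
        xres = page.tags["XResolution"].value
    except KeyError:
        return None
    if hasattr(unit, "value"):
        unit = unit.value
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if den == 0 or num == 0:
        return None
    px_per_unit = num / den
    if unit == _RESUNIT_CM:
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 2.54e4 / px_per_unit
    return None


def write_image_pair(pair: ImagePair, path: str | Path) -> Path:
    """Write an image pair as a 2-page grayscale float TIFF.

    Page order follows the channel convention (elastin first); the pixel
    size is recorded in the resolution tags in pixels/cm.
    """
    path = Path(path)
    res = _resolution_tag(pair.pixel_size)
    with tifffile.TiffWriter(path) as tif:
        for img in (pair.elastin, pair.collagen):
            tif.write(
                img.values.astype(np.float32),
                resolution=res,
                resolutionunit=_RESUNIT_CM,
                metadata=None,
            )
    return path


def read_image_pair(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_order: Sequence[str] = CHANNELS,
) -> ImagePair:
    """Read a 2-page (or 2-channel) TIFF into an :class:`ImagePair`.

    The first page maps to ``channel_order[0]``.  Pixel size comes from
    the TIFF resolution tags unless ``pixel_size_override`` is given; a
    file with neither requires the override.
    """
    path = Path(path)
    if sorted(channel_order) != sorted(CHANNELS):
        raise ValueError(f"channel_order must be a permutation of {CHANNELS}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        if len(pages) >= 2:
            arrays = [pages[0].asarray(), pages[1].asarray()]
            tag_px = _pixel_size_from_tags(pages[0])
        else:
            arr = pages[0].asarray()
            if arr.ndim == 3 and arr.shape[0] >= 2:
                arrays = [arr[0], arr[1]]
            elif arr.ndim == 3 and arr.shape[-1] >= 2:
                arrays = [arr[..., 0], arr[..., 1]]
            else:
                raise MissingChannelError(
                    f"{path} has a single channel; both elastin and collagen "
                    "channels are required"
                )
            tag_px = _pixel_size_from_tags(pages[0])
    if arrays[0].shape != arrays[1].shape:
        raise ValueError("channel dimensions differ")
    pixel_size = pixel_size_override if pixel_size_override is not None else tag_px
    if pixel_size is None:
        raise ValueError(
            f"{path} carries no resolution tags; pass pixel_size_override"
        )
    by_channel = dict(zip(channel_order, arrays))
    return ImagePair(
        elastin=IntensityImage(by_channel["elastin"], pixel_size, "elastin"),
        collagen=IntensityImage(by_channel["collagen"], pixel_size, "collagen"),
    )


def write_feature_map(
    fmap: FeatureMap, path: str | Path, png: bool = True, cmap: str = "viridis"
) -> Path:
    """Write a feature map as a lossless float TIFF plus a PNG rendering.

    The TIFF keeps exact float values with NaN marking background.  The
    PNG uses the map's declared range as fixed color limits so that maps
    of the same feature are directly comparable across samples.
    """
    path = Path(path)
    res = _resolution_tag(fmap.pixel_size)
    tifffile.imwrite(
        path,
        fmap.values.astype(np.float32),
        resolution=res,
        resolutionunit=_RESUNIT_CM,
        metadata={"feature": fmap.name, "vrange": list(fmap.vrange)},
    )
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
        im = ax.imshow(
            fmap.values, cmap=cmap, vmin=fmap.vrange[0], vmax=fmap.vrange[1],
            interpolation="nearest",
        )
        ax.set_axis_off()
        label = fmap.name + (f" [{fmap.units}]" if fmap.units else "")
        fig.colorbar(im, ax=ax, label=label, shrink=0.8)
        fig.savefig(path.with_suffix(".png"), bbox_inches="tight")
        plt.close(fig)
    return path


def read_feature_map(
    path: str | Path,
    name: str,
    vrange: tuple[float, float],
    pixel_size_override: float | None = None,
) -> FeatureMap:
    """Read a float TIFF written by :func:`write_feature_map`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        values = tif.pages[0].asarray().astype(float)
        tag_px = _pixel_size_from_tags(tif.pages[0])
    pixel_size = pixel_size_override if pixel_size_override is not None else tag_px
    if pixel_size is None:
        raise ValueError(f"{path} carries no resolution tags")
    return FeatureMap(name=name, values=values, pixel_size=pixel_size, vrange=vrange)


def export_histogram(fmap: FeatureMap, n_bins: int = 50) -> pd.DataFrame:
    """Histogram of a feature map over its defined (mask) pixels.

    Bins span the map's declared range; counts sum to the number of mask
    pixels.  Returns a frame with ``bin_center`` and ``count`` columns.
    """
    vals = fmap.defined
    if vals.size == 0:
        raise ValueError(f"{fmap.name} map has an empty mask")
    counts, edges = np.histogram(vals, bins=n_bins, range=fmap.vrange)
    # np.histogram drops values outside `range`; the declared-range
    # invariant makes that impossible, but guard against float slop.
    counts[-1] += int(vals.size - counts.sum())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "count": counts})
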