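"""Fiber segmentation and pixel-wise morphological feature maps.

Five maps are computed per channel (thickness on the elastin channel
only):

* **LC** — local coverage: fraction of fiber pixels inside a circular
  window, a density proxy in [0, 1].
* **Ori** — local fiber axis from structure-tensor eigen-analysis,
  axial angle in [0, 180)° measured counter-clockwise from the image
  x-axis.
* **DV** — directional variance: 1 minus the mean resultant length of
  doubled orientation angles in a circular window; 0 = perfectly
  aligned, 1 = isotropic.
* **Wav** — waviness: 1 − chord/arc over skeleton segments of fixed
  arc length, propagated from the skeleton to every fiber pixel;
  0 = straight.
* **Thickness** — twice the medial-axis distance (μm), propagated from
  the skeleton; the map maximum serves as the distance scale of the
  resemblance metric.

Windows are clipped at image edges and fractions renormalized by the
in-image window area, so boundary pixels carry no padding bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters, morphology

from .io import FeatureMap, IntensityImage

__all__ = [
    "FeatureConfig",
    "FiberMask",
    "segment_fibers",
    "local_coverage",
    "orientation_map",
    "directional_variance",
    "waviness",
    "thickness_map",
    "channel_feature_maps",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable knobs of segmentation and the feature windows (pixels)."""

    segmentation_method: str = "otsu"
    median_size: int = 3
    min_object_size: int = 8
    window_radius_lc: int = 16
    window_radius_ori: float = 2.0
    window_radius_dv: int = 16
    waviness_segment_length: int = 32

    def __post_init__(self) -> None:
        if self.window_radius_lc < 1 or self.window_radius_dv < 1:
            raise ValueError("window radii must be >= 1")
        if self.window_radius_ori <= 0:
            raise ValueError("orientation window must be positive")
        if self.waviness_segment_length < 2:
            raise ValueError("waviness segment must span >= 2 px")


@dataclass
class FiberMask:
    """Binary fiber mask for one channel."""

    values: np.ndarray
    channel: str
    pixel_size: float
    status: str = "ok"  # "ok" or "empty"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


def segment_fibers(image: IntensityImage, config: FeatureConfig = FeatureConfig()) -> FiberMask:
    """Threshold fibers out of one channel.

    Otsu threshold on the median-filtered intensity, followed by removal
    of objects below ``min_object_size`` pixels.  A constant image cannot
    be thresholded and yields an empty mask with ``status='empty'``.
    """
    vals = image.values
    if np.ptp(vals) == 0:
        return FiberMask(np.zeros(vals.shape, bool), image.channel, image.pixel_size, "empty")
    smoothed = ndimage.median_filter(vals, size=config.median_size)
    if config.segmentation_method != "otsu":
        raise ValueError(f"unknown segmentation method {config.segmentation_method!r}")
    if np.ptp(smoothed) == 0:  # smoothing flattened a nearly-constant image
        return FiberMask(np.zeros(vals.shape, bool), image.channel, image.pixel_size, "empty")
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    mask = morphology.remove_small_objects(mask, max_size=config.min_object_size - 1)
    status = "ok" if mask.any() else "empty"
    return FiberMask(mask, image.channel, image.pixel_size, status)


def _disk_footprint(radius: int) -> np.ndarray:
    return morphology.disk(radius).astype(float)


def _windowed_sum(arr: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    # Zero padding: out-of-image pixels contribute nothing; callers
    # divide by the in-image window area for edge normalization.
    return ndimage.convolve(arr, footprint, mode="constant", cval=0.0)


def local_coverage(mask: FiberMask, config: FeatureConfig = FeatureConfig()) -> FeatureMap:
    """Fraction of fiber pixels in the disk window around each fiber pixel."""
    if not mask.values.any():
        raise ValueError("local coverage undefined on an empty mask")
    fp = _disk_footprint(config.window_radius_lc)
    counts = _windowed_sum(mask.values.astype(float), fp)
    area = _windowed_sum(np.ones_like(mask.values, dtype=float), fp)
    lc = counts / area
    lc[~mask.values] = np.nan
    lc = np.clip(lc, 0.0, 1.0)
    return FeatureMap("LC", lc, mask.pixel_size, (0.0, 1.0), mask.channel)


def orientation_map(
    image: IntensityImage,
    mask: FiberMask,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureMap:
    """Local fiber-axis angle per fiber pixel.

    Eigen-analysis of the Gaussian-smoothed structure tensor: the minor
    eigenvector (lowest intensity variation) is the fiber axis.  Angles
    are axial, in [0, 180)°, counter-clockwise from the x-axis with the
    y-axis up, so a ribbon running toward the upper right reads 45°.
    """
    if not mask.values.any():
        raise ValueError("orientation undefined on an empty mask")
    Arr, Arc, Acc = skfeature.structure_tensor(
        image.values, sigma=config.window_radius_ori, order="rc"
    )
    # Major eigenvector (gradient direction) angle in array coords, then
    # +90° for the fiber axis; negate to convert the y-down grid to the
    # y-up convention.
    grad_angle = 0.5 * np.arctan2(2.0 * Arc, Acc - Arr)
    fiber_angle = -np.degrees(grad_angle) + 90.0
    fiber_angle = np.mod(fiber_angle, 180.0)
    ori = np.where(mask.values, fiber_angle, np.nan)
    return FeatureMap("Ori", ori, mask.pixel_size, (0.0, 180.0), mask.channel, units="deg")


def directional_variance(
    ori: FeatureMap, mask: FiberMask, config: FeatureConfig = FeatureConfig()
) -> FeatureMap:
    """Circular variance of doubled orientation angles in a disk window.

    DV = 1 − R with R the mean resultant length of unit vectors at angle
    2θ over the fiber pixels of the window; doubling makes θ and θ+180°
    equivalent while θ and θ+90° cancel.  An isolated pixel sees only
    itself: R = 1, DV = 0.
    """
    if not mask.values.any():
        raise ValueError("directional variance undefined on an empty mask")
    theta2 = np.where(mask.values, 2.0 * np.radians(ori.values), 0.0)
    theta2 = np.nan_to_num(theta2)
    m = mask.values.astype(float)
    fp = _disk_footprint(config.window_radius_dv)
    c = _windowed_sum(np.cos(theta2) * m, fp)
    s = _windowed_sum(np.sin(theta2) * m, fp)
    n = _windowed_sum(m, fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sqrt(c**2 + s**2) / n
    dv = 1.0 - np.clip(r, 0.0, 1.0)
    dv[~mask.values] = np.nan
    return FeatureMap("DV", dv, mask.pixel_size, (0.0, 1.0), mask.channel)


def _skeleton_branches(skel: np.ndarray) -> list[np.ndarray]:
    """Decompose a skeleton into ordered pixel chains.

    Junction pixels (more than two 8-neighbors) are removed so remaining
    components are simple chains or loops; each is ordered by walking
    from an endpoint (or an arbitrary pixel for loops).
    """
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nbr_count = ndimage.convolve(skel.astype(int), kernel, mode="constant", cval=0)
    chains = skel & ~(skel & (nbr_count > 2))
    labeled, n = ndimage.label(chains, structure=np.ones((3, 3)))
    branches = []
    for lbl in range(1, n + 1):
        coords = np.argwhere(labeled == lbl)
        if len(coords) < 2:
            continue
        pixel_set = {tuple(c) for c in coords}
        # adjacency walk
        def neighbors(p):
            r, c = p
            out = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    q = (r + dr, c + dc)
                    if q in pixel_set:
                        out.append(q)
            return out

        endpoints = [p for p in pixel_set if len(neighbors(p)) == 1]
        start = endpoints[0] if endpoints else next(iter(pixel_set))
        ordered = [start]
        visited = {start}
        current = start
        while True:
            nxt = [q for q in neighbors(current) if q not in visited]
            if not nxt:
                break
            # prefer 4-connected continuation for a cleaner arc length
            nxt.sort(key=lambda q: abs(q[0] - current[0]) + abs(q[1] - current[1]))
            current = nxt[0]
            ordered.append(current)
            visited.add(current)
        if len(ordered) >= 2:
            branches.append(np.array(ordered))
    return branches


def _propagate_from_skeleton(
    values_on_skel: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Assign each mask pixel the value of its nearest valued skeleton pixel."""
    has_value = np.isfinite(values_on_skel)
    if not has_value.any():
        return np.full(mask.shape, np.nan)
    _, (ir, ic) = ndimage.distance_transform_edt(~has_value, return_indices=True)
    out = values_on_skel[ir, ic]
    out[~mask] = np.nan
    return out


def waviness(mask: FiberMask, config: FeatureConfig = FeatureConfig()) -> FeatureMap:
    """Per-pixel fiber waviness: 1 − chord/arc over skeleton windows.

    For each skeleton pixel a window of ``waviness_segment_length``
    pixels of arc, centered on the pixel, defines a segment; waviness is
    one minus the ratio of the segment's endpoint distance (chord) to
    its cumulative length (arc).  Straight segments give 0; values grow
    with curvature and are < 1.  Skeleton values are propagated to all
    fiber pixels via the Euclidean feature transform.
    """
    if not mask.values.any():
        raise ValueError("waviness undefined on an empty mask")
    skel = morphology.skeletonize(mask.values)
    wav_on_skel = np.full(mask.values.shape, np.nan)
    half = config.waviness_segment_length / 2.0
    for branch in _skeleton_branches(skel):
        steps = np.hypot(*np.diff(branch, axis=0).T)
        arclen = np.concatenate([[0.0], np.cumsum(steps)])
        for j, (r, c) in enumerate(branch):
            lo = np.searchsorted(arclen, arclen[j] - half, side="left")
            hi = np.searchsorted(arclen, arclen[j] + half, side="right") - 1
            if hi <= lo:
                wav_on_skel[r, c] = 0.0
                continue
            arc = arclen[hi] - arclen[lo]
            chord = float(np.hypot(*(branch[hi] - branch[lo])))
            wav_on_skel[r, c] = 0.0 if arc == 0 else max(0.0, 1.0 - chord / arc)
    # isolated skeleton pixels (no branch membership) count as straight
    lonely = skel & ~np.isfinite(wav_on_skel)
    wav_on_skel[lonely] = 0.0
    wav = _propagate_from_skeleton(wav_on_skel, mask.values)
    wav = np.clip(wav, 0.0, 1.0)
    wav[~mask.values] = np.nan
    return FeatureMap("Wav", wav, mask.pixel_size, (0.0, 1.0), mask.channel)


def thickness_map(mask: FiberMask) -> FeatureMap:
    """Local fiber width in μm from the medial-axis distance transform.

    At each medial-axis pixel the width is twice the distance to the
    background minus one pixel (so a one-pixel line reads one pixel
    wide); widths propagate from the skeleton to every fiber pixel.
    Only the elastin channel has resolvable individual fibers; passing
    the collagen mask is a contract error.
    """
    if mask.channel != "elastin":
        raise ValueError(
            "thickness is defined for the elastin channel only; "
            f"got {mask.channel!r}"
        )
    if not mask.values.any():
        raise ValueError("thickness undefined on an empty mask")
    skel, dist = morphology.medial_axis(mask.values, return_distance=True)
    width_px = np.where(skel, 2.0 * dist - 1.0, np.nan)
    width_px = np.where(skel, np.maximum(width_px, 1.0), np.nan)
    width = _propagate_from_skeleton(width_px, mask.values) * mask.pixel_size
    hi = float(np.nanmax(width)) if np.isfinite(width).any() else 0.0
    return FeatureMap(
        "Thickness", width, mask.pixel_size, (0.0, max(hi, 1e-9)), mask.channel, units="um"
    )


def channel_feature_maps(
    image: IntensityImage,
    config: FeatureConfig = FeatureConfig(),
    mask: FiberMask | None = None,
) -> tuple[FiberMask, dict[str, FeatureMap]]:
    """Segment one channel and compute its morphology maps.

    Returns the mask and a dict with LC, Ori, DV, Wav (plus Thickness
    for the elastin channel).
    """
    if mask is None:
        mask = segment_fibers(image, config)
    if mask.status == "empty":
        raise ValueError(f"empty fiber mask in {image.channel} channel")
    ori = orientation_map(image, mask, config)
    maps = {
        "LC": local_coverage(mask, config),
        "Ori": ori,
        "DV": directional_variance(ori, mask, config),
        "Wav": waviness(mask, config),
    }
    if image.channel == "elastin":
        maps["Thickness"] = thickness_map(mask)
    return mask, maps
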