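"""Synthetic two-channel fibrous phantoms with ground truth.

No public repository of paired elastin/collagen multiphoton images
exists, so validation runs on generated phantoms whose morphology is
known exactly.  Fibers are random-walk polylines: each fiber draws an
axial base direction from a von Mises distribution (period 180°,
concentration ``orientation_kappa``) and modulates its tangent with a
sinusoid whose amplitude in radians is ``waviness_amplitude``, giving
independent dials for orientation concentration, waviness, thickness
and density.

The collagen channel is either an independent fiber set or, in coupled
mode, a perturbed copy of the elastin paths: each path is displaced by
``coupling_offset`` μm along its local normal and rotated about its
centroid by a random jitter angle.  The two coupling knobs therefore
tune the downstream elastin-collagen resemblance continuously from
identical (offset 0, jitter 0) to unrelated.

Everything is a pure function of (spec, seed): identical inputs give
bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImagePair, IntensityImage, write_image_pair

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "ClassTemplate",
    "CohortSample",
    "generate_fiber_path",
    "generate_phantom_pair",
    "generate_cohort",
    "default_templates",
    "write_cohort",
]

#: Wavelength of the tangent-angle modulation, in μm.
_WAVINESS_WAVELENGTH_UM = 30.0
#: Polyline sampling step, in pixels.
_PATH_STEP_PX = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one two-channel phantom.

    Attributes
    ----------
    image_size
        Pixels per side of the square grid (≥ 32).
    pixel_size
        μm/px.  The default emulates a 210 μm field of view sampled on a
        256 px grid.
    n_fibers_per_channel
        Number of fibers rendered per channel.
    mean_thickness
        Ribbon thickness in μm, either one value for both channels or an
        (elastin, collagen) pair.
    orientation_mean
        Mean axial fiber direction in degrees, in [0, 180).
    orientation_kappa
        von Mises concentration of the base direction; 0 is isotropic.
    waviness_amplitude
        Peak tangent-angle modulation in radians (dimensionless ≥ 0);
        0 gives straight fibers.
    coupling_mode
        ``"independent"`` draws the collagen fibers afresh;
        ``"coupled"`` copies the elastin paths with perturbations.
    coupling_offset
        Normal displacement of the collagen copies, in μm.
    coupling_angle_jitter
        SD in degrees of the per-fiber rotation of the collagen copies.
    intensity_noise_sd
        Additive Gaussian noise SD as a fraction of the maximum
        intensity; clipped back into [0, 1].
    seed
        Seed of the phantom's private random stream.
    """

    image_size: int = 128
    pixel_size: float = 210.0 / 256.0
    n_fibers_per_channel: int = 12
    mean_thickness: float | tuple[float, float] = 2.5
    orientation_mean: float = 90.0
    orientation_kappa: float = 1.0
    waviness_amplitude: float = 0.3
    coupling_mode: str = "independent"
    coupling_offset: float = 0.0
    coupling_angle_jitter: float = 0.0
    intensity_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.n_fibers_per_channel < 1:
            raise ValueError("need at least one fiber per channel")
        for t in self.thickness_pair:
            if not t > 0:
                raise ValueError("mean_thickness must be positive")
        if not 0 <= self.orientation_mean < 180:
            raise ValueError("orientation_mean must be in [0, 180)")
        if self.orientation_kappa < 0 or self.waviness_amplitude < 0:
            raise ValueError("concentration and waviness must be >= 0")
        if self.coupling_mode not in ("independent", "coupled"):
            raise ValueError("coupling_mode must be 'independent' or 'coupled'")
        if self.coupling_offset < 0 or self.coupling_angle_jitter < 0:
            raise ValueError("coupling perturbations must be >= 0")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")

    @property
    def thickness_pair(self) -> tuple[float, float]:
        t = self.mean_thickness
        if isinstance(t, (tuple, list)):
            return float(t[0]), float(t[1])
        return float(t), float(t)


@dataclass
class PhantomPair:
    """A generated phantom: the image pair plus its ground truth."""

    pair: ImagePair
    truth_mask_elastin: np.ndarray
    truth_mask_collagen: np.ndarray
    paths_elastin: list[np.ndarray]
    paths_collagen: list[np.ndarray]
    spec: PhantomSpec


def _sample_axial_angle(rng: np.random.Generator, mean_deg: float, kappa: float) -> float:
    """Draw an axial (period-180°) angle about ``mean_deg``."""
    if kappa == 0:
        return float(rng.uniform(0.0, 180.0))
    # Sample on the doubled circle, halve the deviation: axial von Mises.
    delta = rng.vonmises(0.0, kappa)
    return float((mean_deg + np.degrees(delta) / 2.0) % 180.0)


def generate_fiber_path(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Generate one fiber polyline as an (n, 2) array of (row, col) points.

    The walk starts at a random point of the image and proceeds in both
    directions until it leaves a one-thickness margin around the image or
    exhausts a fixed arc-length budget.  With zero waviness the path is a
    straight segment; increasing ``waviness_amplitude`` bends the tangent
    sinusoidally, lowering the chord/arc ratio.
    """
    size = spec.image_size
    base = np.radians(_sample_axial_angle(rng, spec.orientation_mean, spec.orientation_kappa))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    start = rng.uniform(0.0, size - 1.0, size=2)  # (row, col)
    margin = max(spec.thickness_pair) / spec.pixel_size + 2.0
    max_steps = int(3.0 * size / _PATH_STEP_PX)
    wavelength_px = _WAVINESS_WAVELENGTH_UM / spec.pixel_size

    def walk(direction: float) -> list[np.ndarray]:
        pts = []
        pos = start.copy()
        for i in range(max_steps // 2):
            s = direction * i * _PATH_STEP_PX
            theta = base + spec.waviness_amplitude * np.sin(
                2.0 * np.pi * s / wavelength_px + phase
            )
            # y-up angle convention on a y-down grid: row decreases with sin.
            step = direction * _PATH_STEP_PX * np.array([-np.sin(theta), np.cos(theta)])
            pos = pos + step
            if not (-margin <= pos[0] <= size - 1 + margin
                    and -margin <= pos[1] <= size - 1 + margin):
                break
            pts.append(pos.copy())
        return pts

    forward = walk(+1.0)
    backward = walk(-1.0)
    points = backward[::-1] + [start] + forward
    return np.array(points)


def _render_paths(
    paths: list[np.ndarray], size: int, thickness_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize polylines as anti-aliased ribbons.

    Returns (intensity in [0, 1], boolean ground-truth mask).  Intensity
    ramps linearly from 1 inside the ribbon to 0 over one pixel, so the
    0.5 level set sits at distance thickness/2 from the path.
    """
    occupied = np.zeros((size, size), dtype=bool)
    for path in paths:
        if len(path) == 0:
            continue
        ij = np.rint(path).astype(int)
        keep = (
            (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
        )
        ij = ij[keep]
        occupied[ij[:, 0], ij[:, 1]] = True
    if not occupied.any():
        zeros = np.zeros((size, size))
        return zeros, occupied
    dist = ndimage.distance_transform_edt(~occupied)
    half = thickness_px / 2.0
    intensity = np.clip(half + 0.5 - dist, 0.0, 1.0)
    mask = dist <= half
    return intensity, mask


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate the elastin/collagen image pair for ``spec``.

    In coupled mode each collagen path is the matching elastin path
    displaced by ``coupling_offset`` μm along the normal to its chord
    (random sign) and rotated about its centroid by an angle drawn from
    N(0, ``coupling_angle_jitter``²) degrees.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    t_e, t_c = (t / spec.pixel_size for t in spec.thickness_pair)

    paths_e = [generate_fiber_path(spec, rng) for _ in range(spec.n_fibers_per_channel)]

    if spec.coupling_mode == "independent":
        paths_c = [generate_fiber_path(spec, rng) for _ in range(spec.n_fibers_per_channel)]
    else:
        offset_px = spec.coupling_offset / spec.pixel_size
        paths_c = []
        for path in paths_e:
            new = path.copy()
            if len(new) >= 2 and offset_px > 0:
                chord = new[-1] - new[0]
                norm = np.hypot(*chord)
                if norm > 0:
                    normal = np.array([-chord[1], chord[0]]) / norm
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    new = new + sign * offset_px * normal
            if spec.coupling_angle_jitter > 0 and len(new) >= 2:
                ang = np.radians(rng.normal(0.0, spec.coupling_angle_jitter))
                c, s = np.cos(ang), np.sin(ang)
                centroid = new.mean(axis=0)
                rel = new - centroid
                rot = np.column_stack(
                    [rel[:, 0] * c - rel[:, 1] * s, rel[:, 0] * s + rel[:, 1] * c]
                )
                new = centroid + rot
            paths_c.append(new)

    img_e, mask_e = _render_paths(paths_e, size, t_e)
    img_c, mask_c = _render_paths(paths_c, size, t_c)

    if spec.intensity_noise_sd > 0:
        img_e = np.clip(img_e + rng.normal(0.0, spec.intensity_noise_sd, img_e.shape), 0, 1)
        img_c = np.clip(img_c + rng.normal(0.0, spec.intensity_noise_sd, img_c.shape), 0, 1)

    pair = ImagePair(
        elastin=IntensityImage(img_e, spec.pixel_size, "elastin"),
        collagen=IntensityImage(img_c, spec.pixel_size, "collagen"),
    )
    return PhantomPair(pair, mask_e, mask_c, paths_e, paths_c, spec)


@dataclass(frozen=True)
class ClassTemplate:
    """Sampling ranges of phantom parameters for one tissue class.

    ``ranges`` maps :class:`PhantomSpec` field names to either a fixed
    value or a (low, high) interval sampled uniformly per sample.
    """

    label: str
    ranges: dict = field(default_factory=dict)

    def sample_spec(self, rng: np.random.Generator, **overrides) -> PhantomSpec:
        params: dict = {}
        for key, val in self.ranges.items():
            if isinstance(val, tuple) and len(val) == 2 and all(
                isinstance(v, (int, float)) for v in val
            ):
                params[key] = float(rng.uniform(*val))
            else:
                params[key] = val
        params.update(overrides)
        params["seed"] = int(rng.integers(0, 2**31 - 1))
        return PhantomSpec(**params)


@dataclass
class CohortSample:
    sample_id: str
    label: str
    phantom: PhantomPair


def default_templates(image_size: int = 128) -> list[ClassTemplate]:
    """Templates emulating the three skin tissue classes.

    All morphology dials are shared; the classes differ only in the
    elastin-collagen coupling strength, ordered so that resemblance is
    highest for keloid-like and lowest for normal-like samples:
    keloid tight coupling (sub-μm offset), adjacent intermediate,
    normal weak (large offset).
    """
    common = dict(
        image_size=image_size,
        n_fibers_per_channel=10,
        mean_thickness=2.5,
        orientation_kappa=1.0,
        waviness_amplitude=0.25,
        coupling_mode="coupled",
        intensity_noise_sd=0.02,
    )
    return [
        ClassTemplate("normal", dict(common, coupling_offset=(9.0, 11.0),
                                     coupling_angle_jitter=(35.0, 45.0))),
        ClassTemplate("adjacent", dict(common, coupling_offset=(3.5, 4.5),
                                       coupling_angle_jitter=(10.0, 14.0))),
        ClassTemplate("keloid", dict(common, coupling_offset=(0.2, 0.8),
                                     coupling_angle_jitter=(0.0, 2.0))),
    ]


def generate_cohort(
    templates: list[ClassTemplate], n_per_class: int, seed: int
) -> list[CohortSample]:
    """Generate a reproducible multi-class phantom cohort.

    Each sample draws its own :class:`PhantomSpec` from its class
    template; the per-sample specs are retained for provenance.
    """
    if not templates:
        raise ValueError("template list is empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    labels = [t.label for t in templates]
    if len(set(labels)) != len(labels):
        raise ValueError("template labels must be unique")
    rng = np.random.default_rng(seed)
    samples = []
    for template in templates:
        for i in range(n_per_class):
            spec = template.sample_spec(rng)
            samples.append(
                CohortSample(
                    sample_id=f"{template.label}_{i:03d}",
                    label=template.label,
                    phantom=generate_phantom_pair(spec),
                )
            )
    return samples


def cohort_manifest(samples: list[CohortSample]) -> pd.DataFrame:
    """Per-sample spec table (id, label, every phantom parameter)."""
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "label": s.label}
        spec = asdict(s.phantom.spec)
        spec["mean_thickness"] = str(spec["mean_thickness"])
        row.update(spec)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(samples: list[CohortSample], out_dir: str | Path) -> pd.DataFrame:
    """Write each pair as a 2-page TIFF plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(samples)
    paths = []
    for s in samples:
        p = out_dir / f"{s.sample_id}.tif"
        write_image_pair(s.phantom.pair, p)
        paths.append(p.name)
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
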