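import warnings

import numpy as np
import pytest

from fibersim import (
    ModelConfig,
    PhantomSpec,
    default_templates,
    generate_cohort,
    generate_phantom_pair,
)
from fibersim.features import FiberMask
from fibersim.io import FeatureMap, IntensityImage
from fibersim.stats import cohort_feature_table

warnings.filterwarnings("ignore", category=FutureWarning)


def ribbon_mask(size: int, angle_deg: float, half_width: int = 3) -> np.ndarray:
    """Straight ribbon through the image center at an axial angle (y-up)."""
    rr, cc = np.mgrid[0:size, 0:size]
    theta = np.radians(angle_deg)
    # signed distance to the line through the center with direction theta
    x = cc - size / 2.0
    y = (size / 2.0) - rr  # y-up
    dist = np.abs(-np.sin(theta) * x + np.cos(theta) * y)
    return dist <= half_width


def as_elastin(mask: np.ndarray, pixel_size: float = 1.0) -> FiberMask:
    return FiberMask(mask, "elastin", pixel_size)


def as_collagen(mask: np.ndarray, pixel_size: float = 1.0) -> FiberMask:
    return FiberMask(mask, "collagen", pixel_size)


def feature_on_mask(
    name: str, values: np.ndarray, mask: np.ndarray, vrange, pixel_size: float = 1.0
) -> FeatureMap:
    vals = np.where(mask, values, np.nan).astype(float)
    return FeatureMap(name, vals, pixel_size, vrange)


@pytest.fixture(scope="session")
def identical_phantom():
    """Coupled phantom with zero perturbation: both channels identical."""
    spec = PhantomSpec(
        image_size=128,
        coupling_mode="coupled",
        coupling_offset=0.0,
        coupling_angle_jitter=0.0,
        intensity_noise_sd=0.0,
        seed=3,
    )
    return generate_phantom_pair(spec)


@pytest.fixture(scope="session")
def cohort():
    """Three-class phantom cohort whose only planted discriminant is coupling."""
    return generate_cohort(default_templates(128), n_per_class=12, seed=11)


@pytest.fixture(scope="session")
def cohort_table(cohort):
    return cohort_feature_table(cohort)


@pytest.fixture(scope="session")
def model_config():
    return ModelConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
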