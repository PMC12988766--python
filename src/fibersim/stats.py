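"""Per-sample statistical indicators of the feature maps.

Each sample reduces to 20 numbers: the mean (overall level) and SD
(scattering level) of ten maps — local coverage, orientation,
directional variance and waviness of both channels, elastin thickness,
and RM.  Statistics run over defined (fiber-mask) pixels only, so
background never enters.

Conventions: pixel-level map SDs use the population definition (the
pixel counts are large); replicate-level coefficients of variation use
the sample (n−1) definition.  Orientation is averaged arithmetically on
[0, 180) to match linear orientation histograms; a circular mean is
available for distributions hugging the 0/180 wrap.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureConfig
from .io import FeatureMap, ImagePair
from .resemblance import RMConfig, compute_rm

__all__ = [
    "MAP_KEYS",
    "FEATURE_COLUMNS",
    "summarize_map",
    "coefficient_of_variation",
    "sample_maps",
    "assemble_table",
    "cohort_feature_table",
]

#: The ten maps each sample must provide, in fixed column order.
MAP_KEYS = (
    "Ela_LC",
    "Ela_Ori",
    "Ela_DV",
    "Ela_Wav",
    "Col_LC",
    "Col_Ori",
    "Col_DV",
    "Col_Wav",
    "Ela_Thickness",
    "RM",
)

#: The 20 statistic columns, mean then SD per map.
FEATURE_COLUMNS = tuple(
    f"{key}_{stat}" for key in MAP_KEYS for stat in ("mean", "sd")
)

LABELS = ("normal", "adjacent", "keloid")


def summarize_map(
    fmap: FeatureMap, circular_orientation: bool = False
) -> tuple[float, float]:
    """Mean and population SD of a map over its defined pixels.

    ``circular_orientation`` switches orientation maps to the axial
    circular mean/SD (doubled-angle convention); the default arithmetic
    mean matches linear histograms but can bias when the distribution
    straddles the 0/180° wrap.
    """
    vals = fmap.defined
    if vals.size < 2:
        raise ValueError(f"{fmap.name}: need >= 2 defined pixels")
    if circular_orientation and fmap.name == "Ori":
        ang = np.radians(2.0 * vals)
        c, s = np.cos(ang).mean(), np.sin(ang).mean()
        mean = float(np.degrees(np.arctan2(s, c)) / 2.0 % 180.0)
        r = float(np.hypot(c, s))
        sd = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(max(r, 1e-300))))) / 2.0)
        return mean, sd
    return float(vals.mean()), float(vals.std(ddof=0))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent over replicate statistics: sample SD / mean × 100.

    Values below 15% are the conventional threshold for good
    reproducibility.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs >= 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def sample_maps(
    pair: ImagePair,
    feature_config: FeatureConfig = FeatureConfig(),
    rm_config: RMConfig = RMConfig(),
) -> dict[str, FeatureMap]:
    """Run the full pipeline on one pair and collect its ten maps."""
    stack, channel_maps = compute_rm(pair, feature_config, rm_config)
    out = {}
    for prefix, ch in (("Ela", "elastin"), ("Col", "collagen")):
        for feat in ("LC", "Ori", "DV", "Wav"):
            out[f"{prefix}_{feat}"] = channel_maps[ch][feat]
    out["Ela_Thickness"] = channel_maps["elastin"]["Thickness"]
    out["RM"] = stack.rm
    return out


def assemble_table(
    samples: Iterable[tuple[str, str, Mapping[str, FeatureMap]]],
    circular_orientation: bool = False,
) -> pd.DataFrame:
    """Build the samples × 20-statistics table.

    Each entry is (sample_id, label, maps); maps must cover every key in
    :data:`MAP_KEYS`.  Column order is fixed: ``sample_id``, ``label``,
    then mean and SD per map in :data:`FEATURE_COLUMNS` order.
    """
    rows = []
    seen: set[str] = set()
    for sample_id, label, maps in samples:
        if sample_id in seen:
            raise ValueError(f"duplicated sample_id {sample_id!r}")
        seen.add(sample_id)
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
        row: dict = {"sample_id": sample_id, "label": label}
        for key in MAP_KEYS:
            if key not in maps:
                raise ValueError(f"sample {sample_id!r} is missing the {key} map")
            mean, sd = summarize_map(maps[key], circular_orientation)
            row[f"{key}_mean"] = mean
            row[f"{key}_sd"] = sd
        rows.append(row)
    if not rows:
        raise ValueError("no samples provided")
    return pd.DataFrame(rows, columns=["sample_id", "label", *FEATURE_COLUMNS])


def cohort_feature_table(
    cohort,
    feature_config: FeatureConfig = FeatureConfig(),
    rm_config: RMConfig = RMConfig(),
) -> pd.DataFrame:
    """Feature table for a generated phantom cohort (one image = one sample)."""
    entries = []
    for sample in cohort:
        maps = sample_maps(sample.phantom.pair, feature_config, rm_config)
        entries.append((sample.sample_id, sample.label, maps))
    return assemble_table(entries)
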