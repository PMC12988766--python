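"""The elastin-collagen resemblance metric (RM).

RM scores, pixel by pixel, how similar the elastin and collagen fiber
networks are in space and morphology.  The computation runs in five
stages:

1. **Bidirectional pairing** — for every elastin fiber pixel, the
   nearest collagen fiber pixel (Euclidean, exact) and vice versa.  The
   nearest-neighbor relation is asymmetric, so both directions are kept.
2. **Difference maps** — at each fiber pixel, the absolute difference
   between its own feature value and that of its paired pixel in the
   other channel.  Orientation differences exceeding 90° wrap to the
   complementary angle.  A distance pseudo-feature uses the pairing
   distance itself.
3. **Fusion** — the two one-sided difference maps merge on the mask
   union: each channel's own value on its exclusive pixels, the average
   where the masks overlap.
4. **Scoring** — each fused difference map normalizes to [0, 1] with a
   feature-appropriate decreasing function; zero difference scores
   highest.  Distances are scaled by *Duplim*, the maximum of the
   elastin thickness map, so the distance score drops to 1/e at one
   maximal fiber width.
5. **Hadamard combination** — RM is the elementwise product of the five
   score maps (optionally weighted as exponents), in [0, 1], defined on
   the mask union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import FeatureConfig, FiberMask, channel_feature_maps, segment_fibers
from .io import FeatureMap, ImagePair

__all__ = [
    "RMConfig",
    "PairingResult",
    "DifferencePair",
    "ScoreStack",
    "bidirectional_pairing",
    "difference_maps",
    "fuse",
    "score_distance",
    "score_coverage",
    "score_orientation",
    "score_collective",
    "compose_rm",
    "compute_rm",
]

E_MINUS_1 = np.e - 1.0

#: Features entering RM, in scoring order.
RM_FEATURES = ("Distance", "LC", "Ori", "DV", "Wav")


@dataclass(frozen=True)
class RMConfig:
    """Knobs of the scoring stage.

    ``contrast_coefficient`` sharpens the collective-feature sigmoid
    around a difference of ½ (default 4).  ``weights`` are per-feature
    exponents on the score maps; all ones reproduces the plain Hadamard
    product.  ``duplim_floor`` (μm), when set, replaces a degenerate
    distance scale instead of raising.  ``shifted_sigmoid=False``
    selects the raw antisymmetric form of the collective score, with
    range (−½, ½), for auditing only: it breaks the [0, 1] RM range.
    """

    contrast_coefficient: float = 4.0
    weights: dict = field(
        default_factory=lambda: {f: 1.0 for f in RM_FEATURES}
    )
    duplim_floor: float | None = None
    shifted_sigmoid: bool = True

    def __post_init__(self) -> None:
        if not self.contrast_coefficient > 0:
            raise ValueError("contrast coefficient must be positive")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be >= 0")
        unknown = set(self.weights) - set(RM_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature weights: {sorted(unknown)}")


@dataclass
class PairingResult:
    """Nearest other-channel pixel, both directions.

    ``dist_at_elastin[p]`` is the distance (μm) from elastin pixel ``p``
    to its nearest collagen pixel, whose (row, col) sits in
    ``index_at_elastin[:, p]``; NaN off the elastin mask.  The collagen
    side is analogous and in general different (the relation is
    asymmetric).
    """

    dist_at_elastin: FeatureMap
    dist_at_collagen: FeatureMap
    index_at_elastin: np.ndarray  # (2, H, W) int
    index_at_collagen: np.ndarray
    pixel_size: float


@dataclass
class DifferencePair:
    """One-sided inter-channel feature differences for one feature."""

    feature: str
    ms_elastin: np.ndarray  # defined (finite) on the elastin mask
    ms_collagen: np.ndarray


@dataclass
class ScoreStack:
    """The five normalized score maps and their product RM."""

    s_distance: FeatureMap
    s_coverage: FeatureMap
    s_orientation: FeatureMap
    s_dv: FeatureMap
    s_waviness: FeatureMap
    rm: FeatureMap
    duplim: float
    provenance: dict = field(default_factory=dict)

    @property
    def scores(self) -> dict[str, FeatureMap]:
        return {
            "Distance": self.s_distance,
            "LC": self.s_coverage,
            "Ori": self.s_orientation,
            "DV": self.s_dv,
            "Wav": self.s_waviness,
        }


def _nearest_on_mask(target_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact EDT to ``target_mask`` with the index of the nearest mask pixel."""
    dist, idx = ndimage.distance_transform_edt(~target_mask, return_indices=True)
    return dist, idx


def bidirectional_pairing(
    mask_e: FiberMask, mask_c: FiberMask, pixel_size: float | None = None
) -> PairingResult:
    """Nearest-neighbor pairing between the two fiber masks, both ways.

    Distances are exact Euclidean (μm); each direction stores the
    coordinates of the matched pixel on the *other* mask.  Both masks
    must be non-empty — RM is undefined otherwise.
    """
    if pixel_size is None:
        pixel_size = mask_e.pixel_size
    for m in (mask_e, mask_c):
        if not m.values.any():
            raise ValueError(f"empty {m.channel} mask: pairing undefined")
    d_to_c, idx_c = _nearest_on_mask(mask_c.values)
    d_to_e, idx_e = _nearest_on_mask(mask_e.values)

    de = np.where(mask_e.values, d_to_c * pixel_size, np.nan)
    dc = np.where(mask_c.values, d_to_e * pixel_size, np.nan)
    hi = float(max(np.nanmax(de), np.nanmax(dc), 1e-9))
    return PairingResult(
        dist_at_elastin=FeatureMap("Distance", de, pixel_size, (0.0, hi), "elastin", "um"),
        dist_at_collagen=FeatureMap("Distance", dc, pixel_size, (0.0, hi), "collagen", "um"),
        index_at_elastin=idx_c,
        index_at_collagen=idx_e,
        pixel_size=pixel_size,
    )


def _wrap_orientation(diff: np.ndarray) -> np.ndarray:
    """Axial angle difference: complement values exceeding 90°."""
    return np.where(diff > 90.0, 180.0 - diff, diff)


def difference_maps(
    feat_e: FeatureMap | None,
    feat_c: FeatureMap | None,
    pairing: PairingResult,
    feature: str | None = None,
) -> DifferencePair:
    """Absolute inter-channel feature differences at paired pixels.

    At each elastin pixel: |own value − value of the nearest collagen
    pixel|, and symmetrically on the collagen side.  Orientation
    differences wrap to the complementary angle above 90°.  For the
    distance pseudo-feature (``feat_e`` and ``feat_c`` both None) the
    underlying feature is identically zero, so the difference reduces to
    the pairing distance itself.
    """
    if feat_e is None and feat_c is None:
        if feature not in (None, "Distance"):
            raise ValueError("missing feature maps for non-distance feature")
        return DifferencePair(
            "Distance",
            pairing.dist_at_elastin.values.copy(),
            pairing.dist_at_collagen.values.copy(),
        )
    if feat_e is None or feat_c is None:
        raise ValueError("both channels' feature maps are required")
    if feat_e.name != feat_c.name:
        raise ValueError(f"feature mismatch: {feat_e.name} vs {feat_c.name}")
    name = feat_e.name

    ir, ic = pairing.index_at_elastin
    partner_at_e = feat_c.values[ir, ic]
    ms_e = np.abs(feat_e.values - partner_at_e)

    jr, jc = pairing.index_at_collagen
    partner_at_c = feat_e.values[jr, jc]
    ms_c = np.abs(feat_c.values - partner_at_c)

    if name == "Ori":
        ms_e = _wrap_orientation(ms_e)
        ms_c = _wrap_orientation(ms_c)
    return DifferencePair(name, ms_e, ms_c)


def fuse(
    diff: DifferencePair, mask_e: FiberMask, mask_c: FiberMask
) -> np.ndarray:
    """Merge the one-sided difference maps onto the mask union.

    Elastin-only pixels keep the elastin-side difference, collagen-only
    pixels the collagen side, and overlap pixels the average of the two;
    pixels off the union are NaN.
    """
    me, mc = mask_e.values, mask_c.values
    overlap = me & mc
    out = np.full(me.shape, np.nan)
    out[me & ~overlap] = diff.ms_elastin[me & ~overlap]
    out[mc & ~overlap] = diff.ms_collagen[mc & ~overlap]
    out[overlap] = 0.5 * (diff.ms_elastin[overlap] + diff.ms_collagen[overlap])
    return out


def _score_map(values: np.ndarray, pixel_size: float, name: str) -> FeatureMap:
    return FeatureMap(name, values, pixel_size, (0.0, 1.0))


def score_distance(
    mfd: np.ndarray, duplim: float, config: RMConfig = RMConfig(), pixel_size: float = 1.0
) -> FeatureMap:
    """Distance score: S = 1 / (1 + (d/Duplim)(e−1)).

    Strictly decreasing in the fused distance d; 1 at contact and 1/e
    when d reaches Duplim, the maximal elastin fiber width, so the score
    decays on the scale of one fiber.
    """
    if not duplim > 0:
        if config.duplim_floor is not None and config.duplim_floor > 0:
            duplim = config.duplim_floor
        else:
            raise ValueError(
                "degenerate distance scale (Duplim <= 0); configure duplim_floor"
            )
    s = 1.0 / (1.0 + (mfd / duplim) * E_MINUS_1)
    return _score_map(s, pixel_size, "S_D")


def score_coverage(mfl: np.ndarray, pixel_size: float = 1.0) -> FeatureMap:
    """Coverage score: S = 1 / (1 + ΔLC·(e−1)), in [1/e, 1]."""
    defined = mfl[np.isfinite(mfl)]
    if defined.size and (defined.min() < -1e-9 or defined.max() > 1 + 1e-9):
        raise ValueError("coverage differences must lie in [0, 1]")
    s = 1.0 / (1.0 + mfl * E_MINUS_1)
    return _score_map(s, pixel_size, "S_L")


def score_orientation(mfo_deg: np.ndarray, pixel_size: float = 1.0) -> FeatureMap:
    """Orientation score: S = cos(Δθ) for Δθ ∈ [0°, 90°]."""
    defined = mfo_deg[np.isfinite(mfo_deg)]
    if defined.size and (defined.min() < -1e-9 or defined.max() > 90 + 1e-9):
        raise ValueError("orientation differences must lie in [0°, 90°]")
    s = np.cos(np.radians(np.clip(mfo_deg, 0.0, 90.0)))
    return _score_map(s, pixel_size, "S_O")


def score_collective(
    mfcd: np.ndarray, config: RMConfig = RMConfig(), pixel_size: float = 1.0, name: str = "S_CD"
) -> FeatureMap:
    """Score for collective-distribution features (ΔDV, ΔWav).

    The shifted sigmoid S = ½[1 − tanh(C(x − ½))] is strictly
    decreasing on [0, 1], passes through ½ at x = ½, and satisfies
    S(x) + S(1−x) = 1; the contrast coefficient C (default 4) sharpens
    the transition around intermediate differences.  The raw
    antisymmetric form −½·tanh(C(x − ½)), selectable with
    ``shifted_sigmoid=False``, is kept for auditing; its (−½, ½) range
    is incompatible with a [0, 1] RM.
    """
    defined = mfcd[np.isfinite(mfcd)]
    if defined.size and (defined.min() < -1e-9 or defined.max() > 1 + 1e-9):
        raise ValueError("collective-feature differences must lie in [0, 1]")
    core = -0.5 * np.tanh(config.contrast_coefficient * (mfcd - 0.5))
    if not config.shifted_sigmoid:
        return FeatureMap(name, core, pixel_size, (-0.5, 0.5))
    return _score_map(core + 0.5, pixel_size, name)


def compose_rm(
    scores: dict[str, FeatureMap],
    config: RMConfig = RMConfig(),
    pixel_size: float = 1.0,
) -> FeatureMap:
    """Hadamard product of the five score maps, weights as exponents.

    With all weights 1 this is the plain elementwise product; weight 0
    removes a feature (its factor becomes 1).
    """
    missing = set(RM_FEATURES) - set(scores)
    if missing:
        raise ValueError(f"missing score maps: {sorted(missing)}")
    ref_mask = scores["Distance"].mask
    rm = np.ones(ref_mask.shape)
    for feat in RM_FEATURES:
        smap = scores[feat]
        if smap.values.shape != ref_mask.shape or not np.array_equal(smap.mask, ref_mask):
            raise ValueError(f"score map {feat} domain differs from the mask union")
        w = config.weights.get(feat, 1.0)
        if w == 0:
            continue
        rm = rm * np.power(smap.values, w)
    rm = np.where(ref_mask, rm, np.nan)
    return _score_map(rm, pixel_size, "RM")


def compute_rm(
    pair: ImagePair,
    feature_config: FeatureConfig = FeatureConfig(),
    rm_config: RMConfig = RMConfig(),
    masks: tuple[FiberMask, FiberMask] | None = None,
) -> tuple[ScoreStack, dict[str, dict[str, FeatureMap]]]:
    """Full RM pipeline on an image pair.

    Segments both channels, computes the morphology maps, pairs the
    masks bidirectionally, differences, fuses, scores, and multiplies.
    Returns the :class:`ScoreStack` (including a provenance record with
    Duplim and all knobs) and the per-channel feature maps.

    Raises if either channel segments to an empty mask, naming the
    channel.
    """
    if masks is not None:
        mask_e, mask_c = masks
    else:
        mask_e = segment_fibers(pair.elastin, feature_config)
        mask_c = segment_fibers(pair.collagen, feature_config)
    for mask, ch in ((mask_e, "elastin"), (mask_c, "collagen")):
        if not mask.values.any():
            raise ValueError(f"empty fiber mask in the {ch} channel; RM undefined")

    _, maps_e = channel_feature_maps(pair.elastin, feature_config, mask=mask_e)
    _, maps_c = channel_feature_maps(pair.collagen, feature_config, mask=mask_c)

    pairing = bidirectional_pairing(mask_e, mask_c, pair.pixel_size)
    duplim = float(np.nanmax(maps_e["Thickness"].values))

    fused: dict[str, np.ndarray] = {}
    for feat in RM_FEATURES:
        if feat == "Distance":
            diff = difference_maps(None, None, pairing)
        else:
            diff = difference_maps(maps_e[feat], maps_c[feat], pairing)
        fused[feat] = fuse(diff, mask_e, mask_c)

    px = pair.pixel_size
    scores = {
        "Distance": score_distance(fused["Distance"], duplim, rm_config, px),
        "LC": score_coverage(fused["LC"], px),
        "Ori": score_orientation(fused["Ori"], px),
        "DV": score_collective(fused["DV"], rm_config, px, name="S_V"),
        "Wav": score_collective(fused["Wav"], rm_config, px, name="S_W"),
    }
    rm = compose_rm(scores, rm_config, px)
    provenance = {
        "duplim_um": duplim,
        "contrast_coefficient": rm_config.contrast_coefficient,
        "weights": dict(rm_config.weights),
        "shifted_sigmoid": rm_config.shifted_sigmoid,
        "feature_config": feature_config.__dict__.copy(),
        "orientation_fusion": "wrap-then-fuse",
        "n_mask_elastin": mask_e.n_pixels,
        "n_mask_collagen": mask_c.n_pixels,
    }
    stack = ScoreStack(
        s_distance=scores["Distance"],
        s_coverage=scores["LC"],
        s_orientation=scores["Ori"],
        s_dv=scores["DV"],
        s_waviness=scores["Wav"],
        rm=rm,
        duplim=duplim,
        provenance=provenance,
    )
    return stack, {"elastin": maps_e, "collagen": maps_c}
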