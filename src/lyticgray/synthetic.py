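"""Synthetic study generator calibrated to the published group statistics.

Two pathology groups (multiple myeloma, MM; osteolytic metastasis, OL) are
crossed with two bone classes (nonflat = 1, flat = 2), giving four strata:
MM1, OL1, MM2, OL2.  The generative model is hierarchical:

  * case level — a case's true mean gray level MGL ~ Normal(mgl_mean,
    mgl_sd) and true within-ROI spread SDGL ~ Normal(sdgl_mean, sdgl_sd),
    drawn independently (no correlation information is published); CVGL is
    always derived per case as SDGL/MGL*100, never drawn directly;
  * pixel level — ROI pixels i.i.d. Normal(MGL, SDGL), rounded and clipped
    to the 12-bit range [0, 4095].

``study_presets`` hard-codes the published group means, standard
deviations, observed ranges and group sizes as the calibration preset.
``generate_radiograph_scene`` renders a full phantom radiograph (smooth
background gradient, brighter bone band, darker elliptical lytic lesion,
additive noise) with the ground-truth ROI, so the entire pipeline -- ROI
extraction, filtering, features, statistics -- runs without patient data.

Every generator is a pure function of (parameters, seed): per-stratum and
per-case random streams are derived from the master seed by stable
hashing, so outputs are reproducible and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .imaging import BoneClass, Group, ImageGrid, ROISpec

__all__ = [
    "GroupDistributionParams",
    "SceneConfig",
    "study_presets",
    "generate_group_cases",
    "render_roi_image",
    "generate_radiograph_scene",
    "simulate_feature_auc",
    "derive_seed",
    "STRATUM_TO_GROUPS",
]

#: Stratum label -> (pathology group, bone class); suffix 1 = nonflat, 2 = flat.
STRATUM_TO_GROUPS: Mapping[str, tuple[Group, BoneClass]] = {
    "MM1": (Group.MM, BoneClass.NONFLAT),
    "OL1": (Group.OL, BoneClass.NONFLAT),
    "MM2": (Group.MM, BoneClass.FLAT),
    "OL2": (Group.OL, BoneClass.FLAT),
}

_SDGL_FLOOR = 1.0  # gray levels; truncation floor for pathological draws


@dataclass(frozen=True)
class GroupDistributionParams:
    """Per-stratum generative parameters (gray-level units).

    mgl_range / sdgl_range are the published observed min/max, kept as a
    sanity range; they are not truncation bounds unless ``truncate`` is set.
    """

    label: str
    mgl_mean: float
    mgl_sd: float
    sdgl_mean: float
    sdgl_sd: float
    cvgl_mean: float
    cvgl_sd: float
    n_cases: int
    mgl_range: tuple[float, float] = (0.0, 4095.0)
    sdgl_range: tuple[float, float] = (0.0, 4095.0)
    truncate: bool = False

    def __post_init__(self) -> None:
        if self.label not in STRATUM_TO_GROUPS:
            raise ValueError(f"unknown stratum label {self.label!r}")
        if min(self.mgl_sd, self.sdgl_sd, self.cvgl_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")

    @property
    def group(self) -> Group:
        return STRATUM_TO_GROUPS[self.label][0]

    @property
    def bone_class(self) -> BoneClass:
        return STRATUM_TO_GROUPS[self.label][1]


def study_presets() -> dict[str, GroupDistributionParams]:
    """Calibration presets: published per-stratum gray-level statistics.

    Means and standard deviations of the case-level MGL/SDGL/CVGL
    distributions and the stratum sizes of the source radiographic study
    of lytic lesions (MM vs OL, nonflat vs flat bone).
    """
    return {
        "MM1": GroupDistributionParams(
            label="MM1", n_cases=31,
            mgl_mean=1710.42, mgl_sd=332.25, mgl_range=(1264, 2017),
            sdgl_mean=256.89, sdgl_sd=12.98, sdgl_range=(242.37, 277.56),
            cvgl_mean=15.02, cvgl_sd=3.09,
        ),
        "OL1": GroupDistributionParams(
            label="OL1", n_cases=35,
            mgl_mean=1634.13, mgl_sd=269.36, mgl_range=(1312, 2000),
            sdgl_mean=258.56, sdgl_sd=20.43, sdgl_range=(228.64, 295.52),
            cvgl_mean=16.14, cvgl_sd=2.41,
        ),
        "MM2": GroupDistributionParams(
            label="MM2", n_cases=36,
            mgl_mean=1593.21, mgl_sd=140.87, mgl_range=(1406, 1840),
            sdgl_mean=248.12, sdgl_sd=9.51, sdgl_range=(238.10, 264.27),
            cvgl_mean=15.57, cvgl_sd=1.45,
        ),
        "OL2": GroupDistributionParams(
            label="OL2", n_cases=41,
            mgl_mean=1744.53, mgl_sd=176.75, mgl_range=(1472, 2096),
            sdgl_mean=270.66, sdgl_sd=16.80, sdgl_range=(240.64, 301.28),
            cvgl_mean=15.64, cvgl_sd=1.56,
        ),
    }


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable sub-seed from (master seed, tokens); independent of call order."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            entropy.extend(t.encode("utf-8"))
        else:
            entropy.append(int(t))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def generate_group_cases(params: GroupDistributionParams, seed: int) -> np.ndarray:
    """Draw per-case (mgl, sdgl, cvgl) triples for one stratum.

    Returns an (n_cases, 3) array.  MGL and SDGL are independent normals;
    SDGL draws are truncated at a small positive floor; CVGL is derived.
    With ``params.truncate`` the draws are additionally clipped to the
    published observed ranges.
    """
    rng = np.random.default_rng(derive_seed(seed, params.label, "cases"))
    n = params.n_cases
    mgl = rng.normal(params.mgl_mean, params.mgl_sd, size=n)
    sdgl = rng.normal(params.sdgl_mean, params.sdgl_sd, size=n)
    # Floor guards against negative draws; a deliberately degenerate
    # (sd-free) configuration keeps its exact zero.
    sdgl = np.maximum(sdgl, _SDGL_FLOOR if params.sdgl_sd > 0 else 0.0)
    if params.truncate:
        mgl = np.clip(mgl, *params.mgl_range)
        sdgl = np.clip(sdgl, *params.sdgl_range)
    mgl = np.maximum(mgl, _SDGL_FLOOR)  # keep CVGL defined
    cvgl = sdgl / mgl * 100.0
    return np.column_stack([mgl, sdgl, cvgl])


def render_roi_image(mgl: float, sdgl: float, height: int = 50, width: int = 40,
                     seed: int = 0, bit_depth: int = 12) -> ImageGrid:
    """Render a ROI of i.i.d. Normal(mgl, sdgl) pixels, rounded and clipped.

    For 40x50 ROIs at the study's parameter scale, the empirical features
    recover (mgl, sdgl) to within sampling error (SE_mgl = sdgl/sqrt(2000)).
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    if not (0 < mgl < (1 << bit_depth) - 1):
        raise ValueError("mgl must lie inside the representable gray range")
    if sdgl < 0:
        raise ValueError("sdgl must be >= 0")
    rng = np.random.default_rng(seed)
    vals = rng.normal(mgl, sdgl, size=(height, width))
    vals = np.clip(np.rint(vals), 0, (1 << bit_depth) - 1)
    return ImageGrid(pixels=vals.astype(np.uint16), bit_depth=bit_depth)


@dataclass(frozen=True)
class SceneConfig:
    """Phantom radiograph layout (all gray levels in 12-bit units).

    The scene is a smooth horizontal background gradient, a brighter
    horizontal bone band, and a darker elliptical lytic lesion centered in
    the band.  Within-lesion texture has standard deviation ``lesion_sdgl``;
    pixels outside the lesion get additive Normal(0, noise_sd) noise.
    """

    height: int = 128
    width: int = 128
    background_level: float = 900.0
    gradient_amplitude: float = 100.0
    band_level: float = 2400.0
    band_top: int = 14
    band_bottom: int = 114
    lesion_center: tuple[int, int] = (64, 64)   # (row, col)
    lesion_axes: tuple[int, int] = (38, 31)     # (semi-height b, semi-width a)
    lesion_mgl: float = 1600.0
    lesion_sdgl: float = 250.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.lesion_center
        b, a = self.lesion_axes
        if a < 1 or b < 1:
            raise ValueError("lesion axes must be >= 1 pixel")
        if r - b < 0 or r + b >= self.height or c - a < 0 or c + a >= self.width:
            raise ValueError("lesion ellipse extends outside the image")
        if not (self.lesion_mgl < self.band_level):
            raise ValueError("lytic lesion must be darker than the bone band")


def ground_truth_roi(config: SceneConfig, roi_width: int = 40, roi_height: int = 50) -> ROISpec:
    """The study-default ROI centered on the lesion, fully inside the ellipse.

    An axis-aligned roi_width x roi_height rectangle centered at the lesion
    center; raises if its corners fall outside the lesion, since the ROI is
    meant to sample lesion tissue only.
    """
    r0, c0 = config.lesion_center
    b, a = config.lesion_axes
    hw, hh = roi_width / 2.0, roi_height / 2.0
    if (hw / a) ** 2 + (hh / b) ** 2 > 1.0:
        raise ValueError(f"{roi_width}x{roi_height} ROI does not fit inside the lesion ellipse")
    return ROISpec(x0=int(round(c0 - hw)), y0=int(round(r0 - hh)), width=roi_width, height=roi_height)


def generate_radiograph_scene(config: SceneConfig) -> tuple[ImageGrid, ROISpec]:
    """Render a phantom radiograph and return it with the ground-truth ROI.

    Deterministic for a given ``config.seed``.  The lesion interior is
    Normal(lesion_mgl, lesion_sdgl); everything else is the structural
    scene plus Normal(0, noise_sd) noise; values rounded and clipped to
    [0, 4095].
    """
    h, w = config.height, config.width
    rng = np.random.default_rng(derive_seed(config.seed, "scene"))
    cols = np.arange(w, dtype=float)
    ramp = config.gradient_amplitude * cols / max(w - 1, 1)
    img = np.full((h, w), config.background_level, dtype=float) + ramp[None, :]
    img[config.band_top:config.band_bottom, :] = config.band_level + ramp[None, :]
    r0, c0 = config.lesion_center
    b, a = config.lesion_axes
    rows = np.arange(h, dtype=float)
    mask = ((rows[:, None] - r0) / b) ** 2 + ((cols[None, :] - c0) / a) ** 2 <= 1.0
    noise = rng.normal(0.0, config.noise_sd, size=(h, w)) if config.noise_sd > 0 else 0.0
    img = img + noise
    lesion = rng.normal(config.lesion_mgl, config.lesion_sdgl, size=(h, w)) \
        if config.lesion_sdgl > 0 else np.full((h, w), config.lesion_mgl)
    img[mask] = lesion[mask]
    img = np.clip(np.rint(img), 0, 4095).astype(np.uint16)
    return ImageGrid(pixels=img, bit_depth=12), ground_truth_roi(config)


def simulate_feature_auc(pos: GroupDistributionParams, neg: GroupDistributionParams,
                         feature: str, n_replicates: int = 2000, seed: int = 0) -> np.ndarray:
    """Monte Carlo distribution of the empirical AUC for one feature.

    Each replicate draws per-case feature values for both strata from the
    calibrated normal models (for ``cvgl`` the published CVGL row is
    sampled directly, since CVGL is a ratio statistic whose derived
    distribution is only approximately normal) and computes the
    tie-corrected Mann-Whitney AUC with the positive stratum first.
    Returns the array of replicate AUCs; its mean estimates the expected
    finite-sample AUC, which for normal models equals the binormal value.
    """
    from .stats import empirical_auc  # local import to avoid a cycle at module load

    if feature not in ("mgl", "sdgl", "cvgl"):
        raise ValueError("feature must be one of 'mgl', 'sdgl', 'cvgl'")
    mu_p, sd_p = getattr(pos, f"{feature}_mean"), getattr(pos, f"{feature}_sd")
    mu_n, sd_n = getattr(neg, f"{feature}_mean"), getattr(neg, f"{feature}_sd")
    rng = np.random.default_rng(derive_seed(seed, "auc", feature, pos.label, neg.label))
    aucs = np.empty(n_replicates)
    for i in range(n_replicates):
        p = rng.normal(mu_p, sd_p, size=pos.n_cases)
        n = rng.normal(mu_n, sd_n, size=neg.n_cases)
        aucs[i] = empirical_auc(p, n).auc
    return aucs


def scene_for_case(mgl: float, sdgl: float, seed: int, base: SceneConfig | None = None) -> SceneConfig:
    """A per-case scene: the default layout with this case's lesion targets.

    The bone band is raised if needed so the lytic lesion stays darker
    than the surrounding band for unusually bright cases.
    """
    base = base or SceneConfig()
    band = max(base.band_level, min(float(np.ceil(mgl)) + 300.0, 4095.0))
    return replace(base, lesion_mgl=float(mgl), lesion_sdgl=float(sdgl),
                   band_level=band, seed=int(seed))
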