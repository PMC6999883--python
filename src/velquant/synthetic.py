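"""Synthetic autofluorescence scenes and feature datasets.

Real VELscope-style images of oral lesions are not publicly deposited, so
this module generates stand-ins with the statistical structure the
analysis assumes:

* three lesion classes — normal (N), premalignant (PM), malignant (M) —
  at two oral subsites (tongue, buccal mucosa);
* class-dependent fluorescence patterns: N retains pale-green
  fluorescence (FVR, bright ROI), M loses it (FVL, dark ROI), PM shows
  increased fluorescence (FVI) or a mixed FVI-periphery/FVL-core pattern
  typical of erythroleukoplakia;
* class-dependent heterogeneity (within-ROI standard deviation);
* bright non-ROI confounders (teeth, device, prosthesis) plus a per-image
  ambient stray-light offset and illumination gain — the nuisances that
  motivate ratio normalization.

The rendered signal is green-dominant: the gray profile is placed in the
G channel and the R and B channels carry fixed low fractions of it.

None of the default parameters are estimates of the clinical data; they
are a plausible parameterization chosen so that the classes are
QDA-separable but not trivially linearly separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .exceptions import NotPositiveDefiniteError, ROIError, VelquantError
from .roi import CircleROI

CLASS_LABELS = ("N", "M", "PM")
SUBSITES = ("tongue", "buccal")
Pattern = Literal["FVR", "FVI", "FVL", "FVI_FVL_mixed"]

#: Fluorescence patterns consistent with each lesion class.
CLASS_PATTERNS: Dict[str, Tuple[str, ...]] = {
    "N": ("FVR",),
    "M": ("FVL",),
    "PM": ("FVI", "FVI_FVL_mixed"),
}

#: Fixed R and B fractions of the green signal in rendered images.
RED_FRACTION = 0.30
BLUE_FRACTION = 0.15

#: Radius fraction of the dark (FVL) core in the mixed PM pattern.
MIXED_CORE_FRACTION = 0.55


# ---------------------------------------------------------------------------
# Feature-space generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassGaussianSpec:
    """Gaussian specification of one class in 2-D feature space.

    The generator-side counterpart of the classifier's per-class mean
    vector, covariance matrix and prior weight.
    """

    class_label: str
    mean: Tuple[float, float]
    covariance: Tuple[Tuple[float, float], Tuple[float, float]]
    prior_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError(f"covariance must be 2x2, got shape {cov.shape}")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise NotPositiveDefiniteError(
                f"covariance is not positive semi-definite (eigenvalues {eigvals})"
            )
        if self.prior_weight < 0:
            raise ValueError(f"prior_weight must be >= 0, got {self.prior_weight}")

    @property
    def mean_array(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    @property
    def covariance_array(self) -> np.ndarray:
        return np.asarray(self.covariance, dtype=float)


def gen_feature_dataset(
    specs: Sequence[ClassGaussianSpec], n_per_class: int, seed: int
) -> pd.DataFrame:
    """Draw a labeled 2-D feature table from per-class Gaussian specs.

    Returns a DataFrame with columns ``intensity``, ``sd`` and ``label``
    holding ``n_per_class`` rows per spec; reproducible for a fixed seed.
    Each covariance must be strictly positive definite.
    """
    if n_per_class < 2:
        raise ValueError(f"n_per_class must be >= 2, got {n_per_class}")
    if not specs:
        raise ValueError("at least one class spec is required")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        cov = spec.covariance_array
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(
                f"covariance of class {spec.class_label!r} is not positive "
                f"definite; sampling requires a full-rank covariance"
            ) from exc
        samples = rng.multivariate_normal(spec.mean_array, cov, size=n_per_class)
        frames.append(
            pd.DataFrame(
                {
                    "intensity": samples[:, 0],
                    "sd": samples[:, 1],
                    "label": spec.class_label,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Image-space generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Confounder:
    """A bright non-ROI artifact: an axis-aligned rectangle or a disc.

    ``params`` is (cx, cy, r) for a disc and (x0, y0, x1, y1) inclusive
    bounds for a rectangle; ``intensity`` is its gray level (near 255).
    """

    kind: Literal["disc", "rect"]
    params: Tuple[float, ...]
    intensity: float

    def paint(self, gray: np.ndarray) -> None:
        h, w = gray.shape
        yy, xx = np.mgrid[0:h, 0:w]
        if self.kind == "disc":
            cx, cy, r = self.params
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        elif self.kind == "rect":
            x0, y0, x1, y1 = self.params
            mask = (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
        else:
            raise ValueError(f"unknown confounder kind {self.kind!r}")
        gray[mask] = self.intensity

    def min_distance_to(self, cx: float, cy: float) -> float:
        """Distance from point (cx, cy) to the closest point of the shape."""
        if self.kind == "disc":
            ccx, ccy, r = self.params
            return max(0.0, float(np.hypot(ccx - cx, ccy - cy)) - r)
        x0, y0, x1, y1 = self.params
        dx = max(x0 - cx, 0.0, cx - x1)
        dy = max(y0 - cy, 0.0, cy - y1)
        return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class ImageSceneSpec:
    """Full description of one synthetic lesion scene.

    The ROI disc receives a class-pattern intensity shift on top of
    ``base_intensity``; ``heterogeneity_sd`` is the standard deviation of
    additive Gaussian noise inside the ROI; ``ambient`` is a stray-light
    offset added to the whole frame and ``gain`` a global illumination
    factor — together they model the nuisances normalization removes.
    """

    subsite: str
    class_label: str
    image_size: Tuple[int, int]  # (height, width)
    roi: CircleROI
    pattern: str
    base_intensity: float = 120.0
    roi_intensity_shift: float = 50.0
    core_intensity_shift: float = -35.0  # FVL core of the mixed PM pattern
    heterogeneity_sd: float = 0.0
    background_noise_sd: float = 0.0
    ambient: float = 0.0
    gain: float = 1.0
    confounders: Tuple[Confounder, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsite not in SUBSITES:
            raise ValueError(f"subsite must be one of {SUBSITES}")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.pattern not in CLASS_PATTERNS[self.class_label]:
            raise ValueError(
                f"pattern {self.pattern!r} is inconsistent with class "
                f"{self.class_label!r}; allowed: {CLASS_PATTERNS[self.class_label]}"
            )
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be nonnegative")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be nonnegative")
        h, w = self.image_size
        r = self.roi
        if r.center_x - r.radius < 0 or r.center_x + r.radius > w - 1:
            raise ROIError("ROI extends beyond image width")
        if r.center_y - r.radius < 0 or r.center_y + r.radius > h - 1:
            raise ROIError("ROI extends beyond image height")
        for conf in self.confounders:
            if conf.min_distance_to(r.center_x, r.center_y) <= r.radius:
                raise ValueError("confounder overlaps the ROI")


def gen_lesion_image(scene: ImageSceneSpec) -> Tuple[np.ndarray, CircleROI, str]:
    """Render a scene to an 8-bit RGB image.

    Deterministic for a fixed ``scene.seed``.  Returns
    ``(image, roi, class_label)`` where ``image`` is (H, W, 3) uint8.
    """
    h, w = scene.image_size
    rng = np.random.default_rng(scene.seed)
    gray = np.full((h, w), float(scene.base_intensity))

    yy, xx = np.mgrid[0:h, 0:w]
    r = scene.roi
    roi_mask = (xx - r.center_x) ** 2 + (yy - r.center_y) ** 2 <= r.radius**2

    if scene.pattern in ("FVR", "FVI", "FVL"):
        gray[roi_mask] = scene.base_intensity + scene.roi_intensity_shift
    elif scene.pattern == "FVI_FVL_mixed":
        core = (xx - r.center_x) ** 2 + (yy - r.center_y) ** 2 <= (
            MIXED_CORE_FRACTION * r.radius
        ) ** 2
        gray[roi_mask] = scene.base_intensity + scene.roi_intensity_shift
        gray[core] = scene.base_intensity + scene.core_intensity_shift
    else:  # pragma: no cover - spec validation forbids this
        raise ValueError(f"unknown pattern {scene.pattern!r}")

    for conf in scene.confounders:
        conf.paint(gray)

    gray += scene.ambient

    # Single named noise stream per scene: unit draws scaled afterwards, so
    # within-ROI spread is monotone in heterogeneity_sd over matched seeds.
    unit_noise = rng.standard_normal((h, w))
    noise = unit_noise * scene.background_noise_sd
    noise[roi_mask] = unit_noise[roi_mask] * scene.heterogeneity_sd
    gray += noise

    gray *= scene.gain
    np.clip(gray, 0.0, 255.0, out=gray)

    rgb = np.empty((h, w, 3))
    rgb[..., 0] = gray * RED_FRACTION
    rgb[..., 1] = gray
    rgb[..., 2] = gray * BLUE_FRACTION
    image = np.rint(rgb).astype(np.uint8)
    return image, r, scene.class_label


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneClassParams:
    """Per-class scene parameterization used by the cohort generator.

    Ranges are uniform per-image sampling intervals: lesions of one class
    vary in fluorescence contrast and heterogeneity, which is what keeps
    the default cohort from being trivially separable.
    """

    pattern: str
    roi_intensity_shift_range: Tuple[float, float]
    core_intensity_shift_range: Tuple[float, float] = (0.0, 0.0)
    heterogeneity_sd_range: Tuple[float, float] = (5.0, 15.0)


#: Default study conditions: N bright and homogeneous (FVR), M dark and
#: heterogeneous (FVL), PM intermediate with a mixed bright-rim/dark-core
#: ROI.  See docs/methods.md for the rationale.
DEFAULT_CLASS_PARAMS: Dict[str, SceneClassParams] = {
    "N": SceneClassParams("FVR", (15.0, 45.0), (0.0, 0.0), (5.0, 18.0)),
    "PM": SceneClassParams("FVI_FVL_mixed", (10.0, 40.0), (-30.0, -5.0), (8.0, 22.0)),
    "M": SceneClassParams("FVL", (-50.0, -15.0), (0.0, 0.0), (12.0, 30.0)),
}

#: Image counts of the reference cohort: five images each of 21 normal,
#: 31 premalignant and 16 malignant cases split across two subsites.
DEFAULT_COHORT_COUNTS: Dict[str, Dict[str, int]] = {
    "tongue": {"N": 55, "PM": 55, "M": 40},
    "buccal": {"N": 50, "PM": 100, "M": 40},
}


@dataclass
class CohortConfig:
    """Configuration of a synthetic image cohort.

    ``counts`` maps subsite -> class -> number of images.  Ranges are
    uniform sampling intervals applied per image.
    """

    counts: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COHORT_COUNTS.items()
        }
    )
    image_size: Tuple[int, int] = (96, 96)
    roi_radius_range: Tuple[float, float] = (18.0, 26.0)
    base_intensity: float = 120.0
    gain_range: Tuple[float, float] = (0.65, 1.35)
    ambient_per_confounder_range: Tuple[float, float] = (8.0, 25.0)
    background_noise_sd: float = 3.0
    confounder_count_range: Tuple[int, int] = (1, 3)
    confounder_intensity_range: Tuple[float, float] = (235.0, 255.0)
    confounder_radius_range: Tuple[float, float] = (5.0, 10.0)
    class_params: Dict[str, SceneClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )

    def total_images(self) -> int:
        return sum(sum(v.values()) for v in self.counts.values())

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "counts": self.counts,
            "image_size": list(self.image_size),
            "roi_radius_range": list(self.roi_radius_range),
            "base_intensity": self.base_intensity,
            "gain_range": list(self.gain_range),
            "ambient_per_confounder_range": list(self.ambient_per_confounder_range),
            "background_noise_sd": self.background_noise_sd,
            "confounder_count_range": list(self.confounder_count_range),
            "confounder_intensity_range": list(self.confounder_intensity_range),
            "confounder_radius_range": list(self.confounder_radius_range),
            "class_params": {
                label: {
                    "pattern": p.pattern,
                    "roi_intensity_shift_range": list(p.roi_intensity_shift_range),
                    "core_intensity_shift_range": list(p.core_intensity_shift_range),
                    "heterogeneity_sd_range": list(p.heterogeneity_sd_range),
                }
                for label, p in self.class_params.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for key in (
            "counts",
            "base_intensity",
            "background_noise_sd",
        ):
            if key in data:
                kwargs[key] = data[key]
        for key in (
            "image_size",
            "roi_radius_range",
            "gain_range",
            "ambient_per_confounder_range",
            "confounder_count_range",
            "confounder_intensity_range",
            "confounder_radius_range",
        ):
            if key in data:
                kwargs[key] = tuple(data[key])
        if "class_params" in data:
            kwargs["class_params"] = {
                label: SceneClassParams(
                    pattern=p["pattern"],
                    roi_intensity_shift_range=tuple(p["roi_intensity_shift_range"]),
                    core_intensity_shift_range=tuple(
                        p.get("core_intensity_shift_range", (0.0, 0.0))
                    ),
                    heterogeneity_sd_range=tuple(p["heterogeneity_sd_range"]),
                )
                for label, p in data["class_params"].items()
            }
        return cls(**kwargs)


@dataclass(frozen=True)
class CohortImage:
    """One generated cohort member."""

    image: np.ndarray
    roi: CircleROI
    label: str
    subsite: str
    image_id: str
    seed: int


def _sample_scene(
    config: CohortConfig,
    subsite: str,
    label: str,
    rng: np.random.Generator,
    scene_seed: int,
) -> ImageSceneSpec:
    h, w = config.image_size
    params = config.class_params[label]
    radius = rng.uniform(*config.roi_radius_range)
    margin = radius + 2.0
    cx = rng.uniform(margin, w - 1 - margin)
    cy = rng.uniform(margin, h - 1 - margin)

    n_conf = int(rng.integers(config.confounder_count_range[0],
                              config.confounder_count_range[1] + 1))
    confounders: List[Confounder] = []
    attempts = 0
    while len(confounders) < n_conf and attempts < 200:
        attempts += 1
        kind = "disc" if rng.random() < 0.5 else "rect"
        intensity = rng.uniform(*config.confounder_intensity_range)
        cr = rng.uniform(*config.confounder_radius_range)
        px = rng.uniform(0, w - 1)
        py = rng.uniform(0, h - 1)
        if kind == "disc":
            cand = Confounder("disc", (px, py, cr), intensity)
        else:
            cand = Confounder(
                "rect",
                (
                    max(0.0, px - cr),
                    max(0.0, py - cr),
                    min(w - 1.0, px + cr),
                    min(h - 1.0, py + cr),
                ),
                intensity,
            )
        if cand.min_distance_to(cx, cy) > radius + 2.0:
            confounders.append(cand)

    ambient = len(confounders) * rng.uniform(*config.ambient_per_confounder_range)
    return ImageSceneSpec(
        subsite=subsite,
        class_label=label,
        image_size=config.image_size,
        roi=CircleROI(cx, cy, radius),
        pattern=params.pattern,
        base_intensity=config.base_intensity,
        roi_intensity_shift=rng.uniform(*params.roi_intensity_shift_range),
        core_intensity_shift=rng.uniform(*params.core_intensity_shift_range),
        heterogeneity_sd=rng.uniform(*params.heterogeneity_sd_range),
        background_noise_sd=config.background_noise_sd,
        ambient=ambient,
        gain=rng.uniform(*config.gain_range),
        confounders=tuple(confounders),
        seed=scene_seed,
    )


def gen_cohort(
    config: CohortConfig,
    seed: int,
    outdir: Optional[Union[str, Path]] = None,
) -> Tuple[List[CohortImage], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns the in-memory images and a manifest DataFrame with columns
    ``path, subsite, class, roi_cx, roi_cy, roi_r, seed``.  When
    ``outdir`` is given, PNGs and ``manifest.csv`` are written there and
    ``path`` points at the files; otherwise ``path`` is empty.
    Fixed ``(config, seed)`` gives bit-identical output.
    """
    rng = np.random.default_rng(seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        try:
            out.mkdir(parents=True, exist_ok=True)
            probe = out / ".write_probe"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise VelquantError(f"output directory {out} is not writable") from exc

    images: List[CohortImage] = []
    rows = []
    for subsite in sorted(config.counts):
        class_counts = config.counts[subsite]
        for label in [c for c in CLASS_LABELS if c in class_counts]:
            for i in range(class_counts[label]):
                scene_seed = int(rng.integers(0, 2**31 - 1))
                scene = _sample_scene(config, subsite, label, rng, scene_seed)
                image, roi, _ = gen_lesion_image(scene)
                image_id = f"{subsite}_{label}_{i:03d}"
                path = ""
                if out is not None:
                    path = f"{image_id}.png"
                    Image.fromarray(image, mode="RGB").save(out / path)
                images.append(
                    CohortImage(image, roi, label, subsite, image_id, scene_seed)
                )
                rows.append(
                    {
                        "path": path,
                        "subsite": subsite,
                        "class": label,
                        "roi_cx": roi.center_x,
                        "roi_cy": roi.center_y,
                        "roi_r": roi.radius,
                        "seed": scene_seed,
                    }
                )
    manifest = pd.DataFrame(
        rows, columns=["path", "subsite", "class", "roi_cx", "roi_cy", "roi_r", "seed"]
    )
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest
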