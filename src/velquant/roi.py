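"""ROI intensity quantification for autofluorescence images.

The analysis reduces each lesion image to two numbers computed over a
clinician-style circular region of interest (ROI): the mean pixel
intensity mu_ROI (brightness) and the sample standard deviation sigma_ROI
(heterogeneity).  Both are optionally normalized by the corresponding
statistics of a reference region,

    mu_norm    = mu_ROI / mu_ref,
    sigma_norm = sigma_ROI / sigma_ref,

which cancels global illumination and hardware variation and neutralizes
stray autofluorescence reaching the ROI from bright non-ROI structures
(teeth, device parts, prostheses).  The reference region is either the
whole gray image (default) or the ROI complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple, Union

import numpy as np

from .exceptions import DegenerateReferenceError, ROIError

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

ChannelMode = Literal["luma", "green"]
ReferenceMode = Literal["whole", "non_roi"]
DegenerateMode = Literal["error", "skip", "epsilon"]

#: Substituted for a zero reference statistic under ``on_degenerate="epsilon"``.
DEGENERATE_EPSILON = 1e-6


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest in pixel coordinates.

    Coordinates are 0-based with ``x`` the column and ``y`` the row; pixel
    centers are integers and membership uses the closed disc
    ``(x - cx)**2 + (y - cy)**2 <= r**2``.
    """

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ROIError(f"ROI radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class MaskROI:
    """Region of interest given as a binary mask (nonzero = selected)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ROIError(f"mask must be 2-D, got shape {m.shape}")
        object.__setattr__(self, "mask", m != 0)


ROISpec = Union[CircleROI, MaskROI]


@dataclass(frozen=True)
class RegionStats:
    """Mean/spread summary of the pixel values selected by a mask.

    ``sd`` uses the sample (N-1 denominator) standard deviation, which is
    why a resolved region must contain at least two pixels.
    """

    mean: float
    sd: float
    n_pixels: int


@dataclass(frozen=True)
class FeatureVector:
    """The 2-D classifier input: (intensity, heterogeneity).

    In un-normalized form the fields are mu_ROI and sigma_ROI in 8-bit
    intensity units; in normalized form they are the dimensionless ratios
    mu_ROI/mu_ref and sigma_ROI/sigma_ref.
    """

    intensity: float
    sd: float
    normalized: bool = False
    subsite: Optional[str] = None
    label: Optional[str] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.intensity, self.sd], dtype=float)


@dataclass(frozen=True)
class ExtractionConfig:
    """How a feature pair is extracted from an RGB image.

    channel
        ``luma`` converts RGB to gray with the BT.601 weights; ``green``
        analyses the G channel directly (the autofluorescence signal is
        green-dominant).
    reference
        ``whole`` normalizes against the entire gray image, ``non_roi``
        against the ROI complement.
    on_degenerate
        What to do when a reference statistic is zero: raise, skip the
        normalized vector (return ``None``), or substitute a small epsilon.
    """

    channel: ChannelMode = "luma"
    reference: ReferenceMode = "whole"
    on_degenerate: DegenerateMode = "error"


def rgb_to_gray(image: np.ndarray, channel_mode: ChannelMode = "luma") -> np.ndarray:
    """Collapse an (H, W, 3) RGB raster to one intensity channel.

    Returns a float64 array in [0, 255].  ``luma`` applies
    0.299 R + 0.587 G + 0.114 B; ``green`` returns the G channel unchanged.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    if channel_mode == "luma":
        w = np.array(LUMA_WEIGHTS)
        return arr @ w
    if channel_mode == "green":
        return arr[..., 1].copy()
    raise ValueError(f"unknown channel mode {channel_mode!r}")


def resolve_mask(roi: ROISpec, height: int, width: int) -> np.ndarray:
    """Resolve an ROI specification to a boolean (height, width) mask.

    A circle must fit entirely inside the image; a mask must match the
    image dimensions; the resolved region must select at least two pixels
    (the sample standard deviation needs N >= 2).
    """
    if isinstance(roi, CircleROI):
        cx, cy, r = roi.center_x, roi.center_y, roi.radius
        # the center must lie on the raster; the disc itself is clipped to
        # the frame, so an over-large radius simply selects every pixel
        if not (0 <= cx <= width - 1 and 0 <= cy <= height - 1):
            raise ROIError(
                f"circle center (cx={cx}, cy={cy}) lies outside a "
                f"{height}x{width} image"
            )
        yy, xx = np.mgrid[0:height, 0:width]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    elif isinstance(roi, MaskROI):
        mask = roi.mask
        if mask.shape != (height, width):
            raise ROIError(
                f"mask shape {mask.shape} does not match image shape "
                f"({height}, {width})"
            )
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported ROI spec {type(roi).__name__}")
    if int(mask.sum()) < 2:
        raise ROIError("ROI selects fewer than 2 pixels; statistics undefined")
    return mask


def region_stats(image: np.ndarray, mask: np.ndarray) -> RegionStats:
    """Mean and sample standard deviation of the masked pixels.

    sd = sqrt( sum |A_i - mu|^2 / (N - 1) ), explicitly with the N-1
    denominator.
    """
    values = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    n = values.size
    if n < 2:
        raise ROIError(f"region statistics need at least 2 pixels, got {n}")
    mean = float(values.mean())
    if values.min() == values.max():
        # constant region: exactly zero spread, immune to summation
        # round-off (which would defeat degenerate-reference detection)
        return RegionStats(mean=float(values[0]), sd=0.0, n_pixels=n)
    sd = float(np.sqrt(np.sum(np.abs(values - mean) ** 2) / (n - 1)))
    return RegionStats(mean=mean, sd=sd, n_pixels=n)


def normalize_features(
    roi_stats: RegionStats,
    reference_stats: RegionStats,
    *,
    on_degenerate: DegenerateMode = "error",
    subsite: Optional[str] = None,
    label: Optional[str] = None,
) -> Optional[FeatureVector]:
    """Form the normalized feature pair (mu_ROI/mu_ref, sigma_ROI/sigma_ref).

    A reference with non-positive mean or zero spread makes the ratios
    undefined; the ``on_degenerate`` policy decides whether that raises,
    yields ``None`` (skip), or substitutes ``DEGENERATE_EPSILON``.
    """
    ref_mean, ref_sd = reference_stats.mean, reference_stats.sd
    if ref_mean <= 0 or ref_sd <= 0:
        if on_degenerate == "error":
            raise DegenerateReferenceError(
                f"degenerate reference region (mean={ref_mean}, sd={ref_sd})"
            )
        if on_degenerate == "skip":
            return None
        if on_degenerate == "epsilon":
            ref_mean = ref_mean if ref_mean > 0 else DEGENERATE_EPSILON
            ref_sd = ref_sd if ref_sd > 0 else DEGENERATE_EPSILON
        else:
            raise ValueError(f"unknown on_degenerate policy {on_degenerate!r}")
    return FeatureVector(
        intensity=roi_stats.mean / ref_mean,
        sd=roi_stats.sd / ref_sd,
        normalized=True,
        subsite=subsite,
        label=label,
    )


def extract_features(
    image: np.ndarray,
    roi: ROISpec,
    config: ExtractionConfig = ExtractionConfig(),
    *,
    subsite: Optional[str] = None,
    label: Optional[str] = None,
) -> Tuple[FeatureVector, Optional[FeatureVector]]:
    """Extract the (un-normalized, normalized) feature pair from one image.

    Returns ``(unnormalized, normalized)``; the second element is ``None``
    when the reference region is degenerate and ``on_degenerate="skip"``.
    """
    gray = rgb_to_gray(image, config.channel)
    height, width = gray.shape
    mask = resolve_mask(roi, height, width)
    roi_stats = region_stats(gray, mask)
    if config.reference == "whole":
        ref_mask = np.ones_like(mask, dtype=bool)
    elif config.reference == "non_roi":
        ref_mask = ~mask
        if int(ref_mask.sum()) < 2:
            raise ROIError("ROI complement selects fewer than 2 pixels")
    else:
        raise ValueError(f"unknown reference mode {config.reference!r}")
    ref_stats = region_stats(gray, ref_mask)
    unnorm = FeatureVector(
        intensity=roi_stats.mean,
        sd=roi_stats.sd,
        normalized=False,
        subsite=subsite,
        label=label,
    )
    norm = normalize_features(
        roi_stats,
        ref_stats,
        on_degenerate=config.on_degenerate,
        subsite=subsite,
        label=label,
    )
    return unnorm, norm
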