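"""Whole-well high-content-screening classification of fluorescent iPSC clones.

A sorted 96-well plate is imaged in three fluorescence channels (blue, green,
red).  Each well mosaic is smoothed per channel with a Gaussian low-pass
filter, thresholded into per-channel positive masks, and classified from the
area proportions of those masks within the clonal region of interest (the
union of the red and green masks).  Wells whose region is at most
``min_clone_area`` pixels are treated as containing no clone.

The class rules, kernel sizes and thresholds follow the screening protocol
for dual-reporter (dTOMATO/EGFP) knock-in clones with a tagBFP random
integration marker:

* ``Red``      — AP_red > 0.9 and AP_green < 0.1
* ``Green``    — AP_red < 0.1 and AP_green > 0.9
* ``RedGreen`` — AP_red > 0.1 and AP_green > 0.1 (the pickable, biallelic wells)
* ``Blue``     — AP_blue > 0.1 (random integration; vetoes every other label)
* ``Negative`` — everything else

All inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

__all__ = [
    "SmoothingSpec",
    "ClassifierConfig",
    "WellMosaic",
    "ChannelMasks",
    "CloneRegion",
    "WellClassification",
    "LABELS",
    "gaussian_lowpass",
    "compute_masks",
    "clone_region",
    "area_proportions",
    "label_from_proportions",
    "classify_well",
    "classify_plate",
]

LABELS = ("NoClone", "Blue", "Red", "Green", "RedGreen", "Negative")


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian low-pass filter: discrete window length and standard deviation.

    The window is sampled symmetrically around ``(kernel_size - 1) / 2`` and
    normalised to unit sum.  For even window lengths the filter origin sits at
    index ``kernel_size // 2``, i.e. the output is shifted by half a pixel;
    at the sigmas used here this shift is far below the mask resolution.
    """

    kernel_size: int
    sigma: float

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {self.kernel_size}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def weights(self) -> np.ndarray:
        """Unit-sum 1-D Gaussian weights."""
        center = (self.kernel_size - 1) / 2.0
        x = np.arange(self.kernel_size, dtype=float) - center
        w = np.exp(-(x**2) / (2.0 * self.sigma**2))
        return w / w.sum()


@dataclass(frozen=True)
class ClassifierConfig:
    """All tunable quantities of the well classifier.

    Defaults are the screening protocol's values: red channel smoothed with a
    size-21 / sigma-7 kernel and thresholded at 125 digital numbers; green and
    blue channels smoothed with size-60 / sigma-20 kernels and thresholded at
    200; a well counts as containing a clone only above 20,000 region pixels;
    the pure-channel / mixed-channel proportion cut-offs are 0.9 and 0.1.
    """

    red_spec: SmoothingSpec = SmoothingSpec(21, 7.0)
    greenblue_spec: SmoothingSpec = SmoothingSpec(60, 20.0)
    red_threshold: float = 125.0
    green_threshold: float = 200.0
    blue_threshold: float = 200.0
    min_clone_area: int = 20_000
    ap_high: float = 0.9
    ap_low: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.ap_low < self.ap_high <= 1.0):
            raise ValueError(
                f"need 0 <= ap_low < ap_high <= 1, got {self.ap_low}, {self.ap_high}"
            )
        for name in ("red_threshold", "green_threshold", "blue_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_clone_area <= 0:
            raise ValueError("min_clone_area must be > 0")


@dataclass
class WellMosaic:
    """One well's pre-stitched three-channel intensity rasters."""

    well_id: str
    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.blue.shape, self.green.shape, self.red.shape}
        if len(shapes) != 1:
            raise ValueError(
                f"well {self.well_id}: channel shapes differ: "
                f"blue {self.blue.shape}, green {self.green.shape}, red {self.red.shape}"
            )
        for name in ("blue", "green", "red"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.size == 0:
                raise ValueError(f"well {self.well_id}: {name} must be a non-empty 2-D raster")
            if np.any(arr < 0):
                raise ValueError(f"well {self.well_id}: {name} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass
class ChannelMasks:
    """Per-channel boolean positivity masks from the smoothed rasters."""

    red_positive: np.ndarray
    green_positive: np.ndarray
    blue_positive: np.ndarray


@dataclass
class CloneRegion:
    """Clonal region of interest: union of the red and green positive masks."""

    mask: np.ndarray
    area: int


@dataclass
class WellClassification:
    well_id: str
    label: str
    ap_red: float
    ap_green: float
    ap_blue: float
    clone_area: int


def gaussian_lowpass(image: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Separable Gaussian low-pass filter with symmetric (reflect) borders.

    Returns a real-valued raster of the input shape.  The border pixels are
    computed on a symmetric extension of the image so that flat wells stay
    flat up to the edge and no artificial darkening deletes mask pixels
    at the well border.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D raster")
    w = spec.weights()
    out = correlate1d(image.astype(float), w, axis=0, mode="reflect")
    out = correlate1d(out, w, axis=1, mode="reflect")
    return out


def compute_masks(mosaic: WellMosaic, config: ClassifierConfig) -> ChannelMasks:
    """Threshold the smoothed channels; strictly-greater comparisons."""
    red_lp = gaussian_lowpass(mosaic.red, config.red_spec)
    green_lp = gaussian_lowpass(mosaic.green, config.greenblue_spec)
    blue_lp = gaussian_lowpass(mosaic.blue, config.greenblue_spec)
    return ChannelMasks(
        red_positive=red_lp > config.red_threshold,
        green_positive=green_lp > config.green_threshold,
        blue_positive=blue_lp > config.blue_threshold,
    )


def clone_region(masks: ChannelMasks) -> CloneRegion:
    """OR of the green and red masks; the blue mask never contributes."""
    mask = masks.green_positive | masks.red_positive
    return CloneRegion(mask=mask, area=int(mask.sum()))


def area_proportions(
    masks: ChannelMasks, region: CloneRegion
) -> tuple[float, float, float]:
    """Per-channel mask pixels divided by region pixels.

    Red and green masks are subsets of the region by construction; the blue
    mask is intersected with the region first so that all three proportions
    share the same denominator and stay within [0, 1].
    """
    if region.area <= 0:
        raise ValueError("area proportions are undefined for an empty clone region")
    ap_red = int(masks.red_positive.sum()) / region.area
    ap_green = int(masks.green_positive.sum()) / region.area
    ap_blue = int((masks.blue_positive & region.mask).sum()) / region.area
    return ap_red, ap_green, ap_blue


def label_from_proportions(
    ap_red: float,
    ap_green: float,
    ap_blue: float,
    clone_area: int,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Apply the class rules to already-computed proportions.

    Precedence: the area gate first (NoClone), then Blue (random integration
    vetoes expansion), then Red, Green, RedGreen, with Negative as the
    remainder.  Every comparison is strict, so a well sitting exactly on a
    cut-off (e.g. AP_red = 0.9) falls through to the next rule.
    """
    if clone_area <= config.min_clone_area:
        return "NoClone"
    if ap_blue > config.ap_low:
        return "Blue"
    if ap_red > config.ap_high and ap_green < config.ap_low:
        return "Red"
    if ap_red < config.ap_low and ap_green > config.ap_high:
        return "Green"
    if ap_red > config.ap_low and ap_green > config.ap_low:
        return "RedGreen"
    return "Negative"


def classify_well(
    mosaic: WellMosaic, config: ClassifierConfig = ClassifierConfig()
) -> WellClassification:
    """Smooth, threshold and classify one well mosaic."""
    masks = compute_masks(mosaic, config)
    region = clone_region(masks)
    if region.area <= config.min_clone_area:
        return WellClassification(mosaic.well_id, "NoClone", 0.0, 0.0, 0.0, region.area)
    ap_red, ap_green, ap_blue = area_proportions(masks, region)
    label = label_from_proportions(ap_red, ap_green, ap_blue, region.area, config)
    return WellClassification(mosaic.well_id, label, ap_red, ap_green, ap_blue, region.area)


def classify_plate(
    mosaics: Iterable[WellMosaic], config: ClassifierConfig = ClassifierConfig()
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every well and return the results table plus the pick list.

    The pick list is the set of wells worth expanding: those classified
    ``RedGreen`` (both reporters present, hence putatively biallelic knock-in,
    and not vetoed by the blue random-integration marker).
    """
    rows = []
    seen: set[str] = set()
    for mosaic in mosaics:
        if mosaic.well_id in seen:
            raise ValueError(f"duplicate well_id {mosaic.well_id!r}")
        seen.add(mosaic.well_id)
        c = classify_well(mosaic, config)
        rows.append(
            {
                "well_id": c.well_id,
                "label": c.label,
                "ap_red": c.ap_red,
                "ap_green": c.ap_green,
                "ap_blue": c.ap_blue,
                "clone_area": c.clone_area,
            }
        )
    table = pd.DataFrame(
        rows, columns=["well_id", "label", "ap_red", "ap_green", "ap_blue", "clone_area"]
    )
    pick_list = table.loc[table["label"] == "RedGreen", "well_id"].tolist()
    return table, pick_list
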