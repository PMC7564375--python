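"""Synthetic well mosaics with planted ground truth.

Emulates post-sort 96-well screening plates: each well raster contains zero
to two soft-edged fluorescent colonies on a dark background, with per-channel
amplitudes chosen so that the intended class label is recovered by the
default classifier at low noise.  Intensities mimic a camera at binning 2:
integer digital numbers, clone amplitudes of order 1000 on a background of 0.

The noise model is additive Gaussian read noise on top of optional Poisson
shot noise — the simplest model that exercises the threshold robustness of
the mask pipeline.  Colony texture and optics are deliberately not modelled
beyond the soft edge.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hcs import WellMosaic

__all__ = [
    "PlantedClone",
    "NoiseModel",
    "PlateTruth",
    "render_well",
    "generate_plate",
    "well_ids",
    "DEFAULT_DIMS",
    "DEFAULT_AMPLITUDE",
]

DEFAULT_DIMS = (960, 960)
DEFAULT_AMPLITUDE = 1000.0

#: Class labels the generator can plant.  ``Negative`` is intentionally
#: absent: with the clonal region defined as the union of the red and green
#: masks, AP_red + AP_green >= 1, so Negative only occurs exactly on the
#: decision boundaries and cannot be planted robustly.
PLANTABLE = ("NoClone", "Blue", "Red", "Green", "RedGreen")


@dataclass(frozen=True)
class PlantedClone:
    """One soft-edged disc colony with per-channel peak amplitudes."""

    center: tuple[float, float]  # (row, col) in pixels
    radius: float
    amp_blue: float = 0.0
    amp_green: float = 0.0
    amp_red: float = 0.0
    edge_width: float = 10.0

    def __post_init__(self) -> None:
        if min(self.amp_blue, self.amp_green, self.amp_red) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.radius <= 0 or self.edge_width < 0:
            raise ValueError("radius must be > 0 and edge_width >= 0")

    def footprint(self, dims: tuple[int, int]) -> np.ndarray:
        """Radial profile: 1 inside the disc, linear roll-off over edge_width."""
        r, c = self.center
        reach = self.radius + self.edge_width
        if not (reach <= r <= dims[0] - 1 - reach and reach <= c <= dims[1] - 1 - reach):
            raise ValueError(
                f"clone at {self.center} with reach {reach:.1f} px does not fit in {dims}"
            )
        rows = np.arange(dims[0], dtype=float)[:, None]
        cols = np.arange(dims[1], dtype=float)[None, :]
        dist = np.hypot(rows - r, cols - c)
        if self.edge_width == 0:
            return (dist <= self.radius).astype(float)
        return np.clip((self.radius + self.edge_width - dist) / self.edge_width, 0.0, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian read noise (DN) plus optional Poisson shot noise."""

    gaussian_sigma: float = 0.0
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


@dataclass
class PlateTruth:
    """Planted ground truth: per-well intended label and clone parameters."""

    labels: dict[str, str]
    clones: dict[str, list[PlantedClone]]
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"well_id": list(self.labels), "label": list(self.labels.values())}
        )


def well_ids(n: int) -> list[str]:
    """Plate coordinates A1, A2, ... row-major over an 8x12 (or larger) grid."""
    cols = 12 if n <= 96 else int(np.ceil(n / 8))
    ids = [f"{r}{c}" for r in string.ascii_uppercase for c in range(1, cols + 1)]
    if n > len(ids):
        raise ValueError(f"cannot label {n} wells")
    return ids[:n]


def render_well(
    well_id: str,
    clones: list[PlantedClone],
    dims: tuple[int, int] = DEFAULT_DIMS,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> WellMosaic:
    """Render one well: background + clone profiles per channel + noise.

    Deterministic for a fixed ``rng`` seed.  Output channels are non-negative
    integer rasters (uint16), as delivered by a camera.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    channels = {name: np.zeros(dims, dtype=float) for name in ("blue", "green", "red")}
    for clone in clones:
        fp = clone.footprint(dims)
        channels["blue"] += clone.amp_blue * fp
        channels["green"] += clone.amp_green * fp
        channels["red"] += clone.amp_red * fp
    for name, img in channels.items():
        if noise.poisson:
            img = rng.poisson(img).astype(float)
        if noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, noise.gaussian_sigma, size=dims)
        channels[name] = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return WellMosaic(well_id, channels["blue"], channels["green"], channels["red"])


def _clone_for_label(
    label: str,
    dims: tuple[int, int],
    rng: np.random.Generator,
    amplitude: float,
    radius_range: tuple[float, float],
) -> list[PlantedClone]:
    """Plant clone(s) realising one intended class label.

    RedGreen wells carry a single clone expressing both reporters
    (biallelic knock-in), not two adjacent single-reporter clones.  Blue
    wells carry the reporters plus the blue backbone marker, mimicking a
    random-integration event in an otherwise dual-positive clone.
    """
    if label == "NoClone":
        return []
    radius = rng.uniform(*radius_range)
    edge = 10.0
    reach = radius + edge + 1
    center = (
        rng.uniform(reach, dims[0] - 1 - reach),
        rng.uniform(reach, dims[1] - 1 - reach),
    )
    amp = amplitude * rng.uniform(0.9, 1.1)
    amps = {
        "Red": dict(amp_red=amp),
        "Green": dict(amp_green=amp),
        "RedGreen": dict(amp_red=amp, amp_green=amp),
        "Blue": dict(amp_red=amp, amp_green=amp, amp_blue=amp),
    }[label]
    return [PlantedClone(center=center, radius=radius, edge_width=edge, **amps)]


def generate_plate(
    class_counts: dict[str, int],
    n_wells: int = 96,
    dims: tuple[int, int] = DEFAULT_DIMS,
    noise: NoiseModel | None = None,
    seed: int = 0,
    amplitude: float = DEFAULT_AMPLITUDE,
    radius_range: tuple[float, float] = (100.0, 150.0),
) -> tuple[list[WellMosaic], PlateTruth]:
    """Generate a plate of mosaics with planted class labels.

    ``class_counts`` maps labels from :data:`PLANTABLE` to well counts; the
    remaining wells are left empty (NoClone).  Well-to-label assignment is a
    deterministic shuffle of the seed.
    """
    counts = dict(class_counts)
    unknown = set(counts) - set(PLANTABLE)
    if unknown:
        raise ValueError(f"cannot plant labels {sorted(unknown)}; supported: {PLANTABLE}")
    n_planted = sum(counts.values())
    if n_planted > n_wells:
        raise ValueError(f"{n_planted} planted wells exceed plate capacity {n_wells}")
    labels = [lab for lab, k in counts.items() for _ in range(k)]
    labels += ["NoClone"] * (n_wells - len(labels))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    ids = well_ids(n_wells)
    mosaics: list[WellMosaic] = []
    truth = PlateTruth(labels={}, clones={}, seed=seed)
    for wid, label in zip(ids, labels):
        clones = _clone_for_label(label, dims, rng, amplitude, radius_range)
        truth.labels[wid] = label
        truth.clones[wid] = clones
        mosaics.append(render_well(wid, clones, dims=dims, noise=noise, rng=rng))
    return mosaics, truth
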