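"""Reading and writing plate images and layouts.

A plate layout CSV maps well ids to image files, either one multi-channel
TIFF per well (column ``path``; channel order declared in the run
configuration) or three single-channel files per well (columns
``blue_path``, ``green_path``, ``red_path``; TIFF or PNG).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .hcs import WellMosaic
from .synthetic_wells import PlateTruth

__all__ = ["read_plate", "write_plate", "write_truth"]


def _read_any(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def read_plate(
    layout_csv: str | Path,
    channel_order: tuple[str, str, str] = ("blue", "green", "red"),
) -> list[WellMosaic]:
    """Load every well listed in a layout CSV into mosaics."""
    layout = pd.read_csv(layout_csv)
    base = Path(layout_csv).parent
    mosaics = []
    for row in layout.itertuples(index=False):
        d = row._asdict()
        wid = str(d["well_id"])
        if "path" in d and isinstance(d["path"], str):
            stack = _read_any(base / d["path"])
            if stack.ndim != 3 or stack.shape[0] != 3:
                raise ValueError(f"well {wid}: expected a 3-channel stack, got {stack.shape}")
            channels = dict(zip(channel_order, stack))
        else:
            channels = {
                name: _read_any(base / d[f"{name}_path"]) for name in ("blue", "green", "red")
            }
        mosaics.append(WellMosaic(wid, channels["blue"], channels["green"], channels["red"]))
    return mosaics


def write_plate(
    mosaics: list[WellMosaic],
    out_dir: str | Path,
    channel_order: tuple[str, str, str] = ("blue", "green", "red"),
) -> Path:
    """Write one multi-channel TIFF per well plus the layout CSV; returns the layout path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in mosaics:
        fname = f"{m.well_id}.tiff"
        stack = np.stack([getattr(m, name) for name in channel_order])
        tifffile.imwrite(out / fname, stack, photometric="minisblack")
        rows.append({"well_id": m.well_id, "path": fname})
    layout_path = out / "plate.csv"
    pd.DataFrame(rows).to_csv(layout_path, index=False)
    return layout_path


def write_truth(truth: PlateTruth, path: str | Path) -> None:
    truth.as_frame().to_csv(path, index=False)
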