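"""File I/O: images (16-bit TIFF / PNG), JSON sidecars, CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import CellImage, GroundTruth


def save_cell_image(image: CellImage, path) -> None:
    """Write as 16-bit TIFF (.tif/.tiff) or PNG, scaled to the full range."""
    path = Path(path)
    px = np.asarray(image.pixels, dtype=float)
    hi = px.max() if px.max() > 0 else 1.0
    data = np.round(px / hi * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        from skimage.io import imsave

        imsave(path, data, check_contrast=False)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_cell_image(path, pixel_size: float = 0.25) -> CellImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        from skimage.io import imread

        data = imread(path)
    return CellImage(pixels=np.asarray(data, dtype=float), pixel_size=pixel_size)


def save_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as f:
        json.dump(dataclasses.asdict(truth), f, indent=1)


def load_ground_truth(path) -> GroundTruth:
    with open(path) as f:
        d = json.load(f)
    d["ellipse_center"] = tuple(d["ellipse_center"])
    d["filament_endpoints"] = [
        (tuple(p0), tuple(p1)) for p0, p1 in d["filament_endpoints"]
    ]
    return GroundTruth(**d)


def save_series(times, values, path, value_name: str = "value") -> None:
    """Two-column CSV with a (time_s, value) header row."""
    pd.DataFrame({"time_s": np.asarray(times),
                  value_name: np.asarray(values)}).to_csv(path, index=False)


def load_series(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def save_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.generic):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=1, default=default)
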