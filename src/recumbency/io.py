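"""Plain-file I/O: trajectory/label CSVs, grayscale PNGs, model/report JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .blur import ImageRecord

TRAJECTORY_COLUMNS = ["pen_id", "t_s", "animal_id", "x_m", "y_m", "detected_standing"]
LABEL_COLUMNS = ["pen_id", "t_s", "coder_id", "code"]


def write_csv(df: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trajectories(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    return df


def read_labels(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "code" not in df.columns:
        raise ValueError("label CSV missing 'code' column")
    return df


def image_filename(pen_id: str, t_s: float) -> str:
    return f"{pen_id}_{t_s:g}.png"


def write_image_png(record: ImageRecord, directory: Path | str) -> Path:
    """Write the pixel grid as an 8-bit grayscale PNG named <pen>_<t_s>.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / image_filename(record.pen_id, record.t_s)
    arr = np.clip(np.asarray(record.pixels, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def read_image_png(path: Path | str, pen_id: str, t_s: float) -> ImageRecord:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return ImageRecord(pen_id=pen_id, t_s=t_s, pixels=arr)


def write_json(obj: dict, path: Path | str) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)
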