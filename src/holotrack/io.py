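"""Reading and writing the package's on-disk formats.

Track tables are delimited text with header
``track_id,channel,frame,t_s,x_nm,y_nm,intensity``; movies are multi-page
16-bit TIFFs (one file per channel) with a JSON sidecar recording frame
times and pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import TRACK_COLUMNS


def write_tracks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRACK_COLUMNS)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return df[TRACK_COLUMNS]


def write_movie(stacks: dict[str, np.ndarray], sidecar: dict, directory) -> dict:
    """Write one TIFF per channel plus a shared JSON sidecar.

    Returns the per-channel file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for channel, stack in stacks.items():
        p = directory / f"movie_{channel}.tif"
        tifffile.imwrite(p, stack)
        paths[channel] = str(p)
    with open(directory / "movie_sidecar.json", "w") as fh:
        json.dump({"files": paths, **sidecar}, fh, indent=2)
    return paths


def read_movie(directory) -> tuple[dict[str, np.ndarray], dict]:
    directory = Path(directory)
    with open(directory / "movie_sidecar.json") as fh:
        sidecar = json.load(fh)
    stacks = {
        channel: tifffile.imread(path)
        for channel, path in sidecar["files"].items()
    }
    return stacks, sidecar


def write_roi(vertices, path) -> None:
    with open(path, "w") as fh:
        json.dump({"polygon_nm": np.asarray(vertices).tolist()}, fh)


def read_roi(path):
    with open(path) as fh:
        return np.asarray(json.load(fh)["polygon_nm"], dtype=float)
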