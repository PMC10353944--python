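"""Readers and writers for the package's on-disk interfaces.

Images travel as TIFF (float32 for derived maps, integer for counts),
tables as CSV with documented headers, polylines/polygons as 2-column
(x, y) CSV vertex lists, gene sets as GMT, and run configuration as TOML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "read_polyline_csv",
    "write_polyline_csv",
    "read_detections_csv",
]


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(path, image, as_float=False) -> None:
    image = np.asarray(image)
    if as_float or np.issubdtype(image.dtype, np.floating):
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        tifffile.imwrite(path, image)


def read_polyline_csv(path) -> np.ndarray:
    """Vertex list from a CSV with ``x`` and ``y`` columns (um)."""
    tbl = pd.read_csv(path)
    if not {"x", "y"}.issubset(tbl.columns):
        raise ValueError(f"{path} needs 'x' and 'y' columns")
    return tbl[["x", "y"]].to_numpy(dtype=float)


def write_polyline_csv(path, vertices) -> None:
    pd.DataFrame(np.asarray(vertices, dtype=float), columns=["x", "y"]).to_csv(
        path, index=False
    )


def read_detections_csv(path) -> pd.DataFrame:
    """Detection table with columns frame, t, x, y (and optional extras)."""
    det = pd.read_csv(path)
    missing = {"frame", "t", "x", "y"} - set(det.columns)
    if missing:
        raise ValueError(f"{path} missing detection columns: {sorted(missing)}")
    return det
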