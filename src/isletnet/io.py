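"""Readers and writers for the pipeline's on-disk formats.

Cell tables are plain CSV with the header
``islet_id,mouse_id,cell_id,cell_type,x_um,y_um,tissue_edge``; rims are a
CSV of WKT POLYGON strings (``islet_id,wkt``), both in μm.  Channel
images are 16-bit grayscale TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import shapely.wkt
import tifffile

from .geometry import CellRecord, IsletMap, RimPolygon

CELLS_COLUMNS = [
    "islet_id",
    "mouse_id",
    "cell_id",
    "cell_type",
    "x_um",
    "y_um",
    "tissue_edge",
]


def write_cohort(cohort: list[IsletMap], cells_path, rims_path) -> None:
    """Write a cohort as a cells CSV plus a rims WKT CSV."""
    rows = []
    rim_rows = []
    for islet in cohort:
        for c in islet.cells:
            rows.append(
                (
                    islet.islet_id,
                    islet.mouse_id,
                    c.cell_id,
                    c.cell_type,
                    c.x,
                    c.y,
                    int(islet.tissue_edge_flag),
                )
            )
        rim_rows.append((islet.islet_id, islet.rim.polygon.wkt))
    pd.DataFrame(rows, columns=CELLS_COLUMNS).to_csv(cells_path, index=False)
    pd.DataFrame(rim_rows, columns=["islet_id", "wkt"]).to_csv(rims_path, index=False)


def read_cohort(cells_path, rims_path) -> list[IsletMap]:
    """Read a cohort written by :func:`write_cohort` (islet order preserved)."""
    cells = pd.read_csv(cells_path, dtype={"islet_id": str, "mouse_id": str, "cell_id": str})
    rims = pd.read_csv(rims_path, dtype={"islet_id": str})
    rim_by_id = {
        r.islet_id: RimPolygon.from_polygon(shapely.wkt.loads(r.wkt))
        for r in rims.itertuples()
    }
    cohort: list[IsletMap] = []
    for islet_id, grp in cells.groupby("islet_id", sort=False):
        if islet_id not in rim_by_id:
            raise ValueError(f"no rim polygon for islet {islet_id!r}")
        recs = [
            CellRecord(r.cell_id, r.cell_type, float(r.x_um), float(r.y_um))
            for r in grp.itertuples()
        ]
        cohort.append(
            IsletMap(
                islet_id=str(islet_id),
                mouse_id=str(grp["mouse_id"].iloc[0]),
                rim=rim_by_id[islet_id],
                cells=recs,
                tissue_edge_flag=bool(grp["tissue_edge"].iloc[0]),
            )
        )
    return cohort


def write_channel_tiff(path, pixels: np.ndarray) -> None:
    """Write a non-negative intensity image as 16-bit grayscale TIFF."""
    arr = np.asarray(pixels)
    if arr.min() < 0:
        raise ValueError("intensities must be non-negative")
    tifffile.imwrite(Path(path), np.clip(arr, 0, 65535).astype(np.uint16))


def read_channel_tiff(path) -> np.ndarray:
    """Read a grayscale TIFF as a float array."""
    return tifffile.imread(Path(path)).astype(float)
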