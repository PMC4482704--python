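"""Readers and writers for the plain-text formats the chain exchanges.

Everything here is deliberately simple text: CSV time series, ESRI ASCII
grids for depth/velocity rasters, CSV edge lists plus a JSON sidecar for
river networks, and JSON for species parameter sets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_hydrograph_csv",
    "write_hydrograph_csv",
    "read_json",
    "write_json",
]


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns ``(data, header)`` where ``data`` is a float array with NODATA
    cells set to NaN and ``header`` holds ncols/nrows/xllcorner/yllcorner/
    cellsize/nodata_value. Row 0 of the array is the top (northernmost) row,
    as in the file.
    """
    path = Path(path)
    header: dict = {}
    with path.open() as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                key = parts[0].lower()
                header[key] = int(parts[1]) if key in {"ncols", "nrows"} else float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float)
    data = np.atleast_2d(data)
    nrows, ncols = header.get("nrows"), header.get("ncols")
    if nrows is not None and ncols is not None and data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(np.isclose(data, nodata), np.nan, data)
    return data, header


def write_ascii_grid(path: str | Path, data: np.ndarray, cellsize: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata_value: float = -9999.0) -> None:
    """Write a 2D array as an ESRI ASCII grid; NaN cells become NODATA."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("grid must be 2D")
    out = np.where(np.isnan(data), nodata_value, data)
    lines = [
        f"ncols {data.shape[1]}",
        f"nrows {data.shape[0]}",
        f"xllcorner {xllcorner:.6f}",
        f"yllcorner {yllcorner:.6f}",
        f"cellsize {cellsize:.6f}",
        f"nodata_value {nodata_value:.1f}",
    ]
    body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in out)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_hydrograph_csv(path: str | Path) -> pd.DataFrame:
    """Read a daily discharge series: columns ``date`` (ISO-8601) and ``q``.

    An optional ``run`` column marks ensemble membership.
    """
    df = pd.read_csv(path)
    if "date" not in df.columns or "q" not in df.columns:
        raise ValueError(f"{path}: expected columns 'date' and 'q'")
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_hydrograph_csv(path: str | Path, dates, q) -> None:
    pd.DataFrame({"date": pd.to_datetime(dates).strftime("%Y-%m-%d"),
                  "q": np.asarray(q, dtype=float)}).to_csv(path, index=False)


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
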