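"""Reading and writing the pipeline's on-disk formats.

Tissue maps travel as single-channel PNG label images (0 = background,
1 = stroma, 2 = tumor) with a JSON sidecar holding the μm-per-pixel
resolution; cell tables and cohort tables as CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import TissueMap

CELL_COLUMNS = ["cell_id", "x_px", "y_px", "marker", "positive"]
VALID_MARKERS = {"tumor_ki67", "cd8"}


def write_tissue_map(tissue: TissueMap, path: str | Path) -> Path:
    """Write the label raster as PNG plus a ``<stem>.meta.json`` sidecar."""
    path = Path(path)
    Image.fromarray(tissue.labels.astype(np.uint8), mode="L").save(path)
    meta = {"resolution_um_per_px": tissue.resolution_um_per_px,
            "labels": {"background": 0, "stroma": 1, "tumor": 2}}
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_tissue_map(path: str | Path) -> TissueMap:
    path = Path(path)
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    sidecar = path.with_suffix(".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"tissue map sidecar {sidecar} missing (holds μm/px resolution)")
    meta = json.loads(sidecar.read_text())
    return TissueMap(labels=labels,
                     resolution_um_per_px=float(meta["resolution_um_per_px"]))


def write_cells(cells: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cells[CELL_COLUMNS].to_csv(path, index=False)
    return path


def read_cells(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell table {path} missing columns {sorted(missing)}")
    bad = set(cells["marker"].unique()) - VALID_MARKERS
    if bad:
        raise ValueError(f"unknown markers in {path}: {sorted(bad)}")
    if not cells["positive"].isin([0, 1]).all():
        raise ValueError(f"positive flag in {path} must be 0/1")
    return cells


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    for col in ("time_months", "event"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table {path} missing column {col!r}")
    return cohort


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
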