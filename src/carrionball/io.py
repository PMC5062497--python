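"""Reading and writing the pipeline's file formats.

Formats
-------
manifest.csv     pair_id, view, path, px_per_mm      (one row per image)
occlusions.csv   pair_id, view, center_x, center_y, radius   (pixels)
scores.csv       pair_id, roundness_top, roundness_side, roundness_overall,
                 area_top_px2, perimeter_top_px, area_side_px2,
                 perimeter_side_px, warnings
study table      the BreedingRecord schema (see inference.REQUIRED_COLUMNS)
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError
from .shape_scoring import OcclusionCircle, RasterImage

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["pair_id", "view", "path", "px_per_mm"]
OCCLUSION_COLUMNS = ["pair_id", "view", "center_x", "center_y", "radius"]
SCORE_COLUMNS = [
    "pair_id",
    "roundness_top",
    "roundness_side",
    "roundness_overall",
    "area_top_px2",
    "perimeter_top_px",
    "area_side_px2",
    "perimeter_side_px",
    "warnings",
]

_FILENAME_RE = re.compile(r"^(?P<pair_id>.+)_(?P<view>top|side)\.(png|tif|tiff)$", re.I)


def load_image(path: str | Path, view: str, px_per_mm: float | None = None) -> RasterImage:
    """Read an 8-bit RGB PNG/TIFF as a RasterImage."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:  # grayscale file: replicate into RGB
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return RasterImage(arr, view=view, px_per_mm=px_per_mm)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    return df


def manifest_from_directory(images_dir: str | Path) -> pd.DataFrame:
    """Build a manifest from ``<pair_id>_top.*`` / ``<pair_id>_side.*`` files.

    The per-view default scale is used (px_per_mm left blank).
    """
    rows = []
    for p in sorted(Path(images_dir).iterdir()):
        m = _FILENAME_RE.match(p.name)
        if m:
            rows.append(
                {
                    "pair_id": m["pair_id"],
                    "view": m["view"].lower(),
                    "path": str(p),
                    "px_per_mm": np.nan,
                }
            )
    if not rows:
        raise InvalidInputError(f"no <pair_id>_top/side images found in {images_dir}")
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def read_occlusions(path: str | Path) -> dict[tuple[str, str], list[OcclusionCircle]]:
    """Read the occlusion CSV into a {(pair_id, view): [circles]} map."""
    df = pd.read_csv(path)
    missing = [c for c in OCCLUSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    out: dict[tuple[str, str], list[OcclusionCircle]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[(str(row.pair_id), row.view)].append(
            OcclusionCircle(row.center_x, row.center_y, row.radius)
        )
    return dict(out)


def read_study_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores[SCORE_COLUMNS].to_csv(path, index=False)
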