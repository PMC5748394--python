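"""Reading radiograph rasters, extracting ROIs, and tabular cohort I/O.

Radiographs arrive as scanned 8- or 16-bit grayscale PNG/TIFF files with a
known scan resolution (default 236 px/cm, i.e. 10/236 mm per pixel).  The
unit of texture analysis is a fixed 650 x 650 pixel region of interest
(2.75 cm x 2.75 cm at the default calibration) cropped around a manually
chosen centre in the mandibular premolar/molar region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .stats import SCORE_CODES, CohortRecord

__all__ = [
    "DEFAULT_PIXEL_SPACING_MM",
    "ROI_SIDE",
    "GrayImage",
    "GrayROI",
    "ROIWindow",
    "load_gray_image",
    "save_gray_image",
    "extract_roi",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
]

#: mm per pixel at the scan resolution of 236 pixels per centimetre.
DEFAULT_PIXEL_SPACING_MM = 10.0 / 236.0

#: Side of the square analysis window, pixels.
ROI_SIDE = 650


@dataclass(eq=False)
class GrayImage:
    """A calibrated 2-D grayscale raster with intensities in [0, 255]."""

    pixels: np.ndarray
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM  # mm per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.isfinite(self.pixels).all():
            raise ValueError("intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(eq=False)
class GrayROI(GrayImage):
    """A square grayscale region of interest."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.height != self.width:
            raise ValueError(
                f"ROI must be square, got {self.height} x {self.width}"
            )

    @property
    def side(self) -> int:
        return self.height


@dataclass(frozen=True)
class ROIWindow:
    """A square crop window centred on a pixel of the source image.

    For the even default side 650 the crop spans rows
    ``center_row - 325 .. center_row + 324`` (and likewise columns).
    """

    center_row: int
    center_col: int
    side: int = ROI_SIDE

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("side must be >= 1")

    @property
    def row_start(self) -> int:
        return self.center_row - self.side // 2

    @property
    def col_start(self) -> int:
        return self.center_col - self.side // 2


def load_gray_image(
    path: str | Path, pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM
) -> GrayImage:
    """Load a PNG or TIFF raster as a calibrated grayscale image.

    Integer images are rescaled to [0, 255] by their dtype's full dynamic
    range (a 16-bit image is divided by 257), so 8-bit values pass through
    unchanged.  RGB inputs are collapsed by the unweighted channel mean.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:
        raise ValueError(f"unreadable raster file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D or RGB raster, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(float) * (255.0 / info.max)
    else:
        arr = arr.astype(float)
    return GrayImage(pixels=arr, pixel_spacing=pixel_spacing)


def save_gray_image(image: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write an image to 8-bit PNG or TIFF (by extension), rounding to int."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    out = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        Image.fromarray(out, mode="L").save(path)


def extract_roi(image: GrayImage, window: ROIWindow) -> GrayROI:
    """Crop the square window from the image; the source is not modified."""
    r0, c0 = window.row_start, window.col_start
    r1, c1 = r0 + window.side, c0 + window.side
    for value, limit, edge in (
        (r0, 0, "top"),
        (c0, 0, "left"),
        (image.height - r1, 0, "bottom"),
        (image.width - c1, 0, "right"),
    ):
        if value < limit:
            raise IndexError(
                f"ROI window exceeds the {edge} edge of the "
                f"{image.height}x{image.width} image"
            )
    crop = image.pixels[r0:r1, c0:c1].copy()
    return GrayROI(pixels=crop, pixel_spacing=image.pixel_spacing)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_CLINICAL = ("age", "weight", "height", "bmi")


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV into typed records.

    Required columns: ``id``, ``score`` (dense|alternating|sparse, case-
    insensitive), ``fracture`` (0|1).  Optional: age, weight, height, bmi
    (missing values are kept as None, not dropped) and any further numeric
    columns, which become entries of ``record.features``.
    """
    df = pd.read_csv(path)
    required = {"id", "score", "fracture"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} lacks columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids in {path}: {dups}")
    feature_cols = [
        c for c in df.columns if c not in required and c not in _CLINICAL
    ]
    records = []
    for idx, row in df.iterrows():
        label = str(row["score"]).strip().lower()
        if label not in SCORE_CODES:
            raise ValueError(
                f"row {idx} of {path}: unknown score {row['score']!r} "
                f"(expected one of {list(SCORE_CODES)})"
            )
        clin = {}
        for c in _CLINICAL:
            if c in df.columns and pd.notna(row[c]):
                clin[c] = float(row[c])
        feats = {
            c: float(row[c]) for c in feature_cols if pd.notna(row[c])
        }
        records.append(
            CohortRecord(
                id=str(row["id"]),
                score=SCORE_CODES[label],
                fracture=int(row["fracture"]),
                features=feats,
                **clin,
            )
        )
    return records


def write_feature_table(records, path: str | Path) -> None:
    """Write (id, FeatureVector) pairs to CSV, one row per ROI.

    Column order is the documented feature schema (see
    ``FeatureVector.to_row``); the file round-trips through
    :func:`read_feature_table`.
    """
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty feature table")
    rows = []
    for rid, fv in records:
        row = {"id": rid}
        row.update(fv.to_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path)
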