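"""Slide, ROI-annotation and cohort-table input/output.

Coordinate convention used throughout the package: arrays are row-major,
0-based, with pixel-centre sampling; a slide and its ROI annotation share
one shape.  Slides are 8-bit RGB only (brightfield scans); anything else is
rejected explicitly rather than converted silently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

ROI_LABELS = (1, 2, 3, 4)
#: Human-readable names of the four regions of interest: anterior superior
#: labrum, mid-portion at the tendon origin (12 o'clock), posterior superior
#: labrum, and the most proximal long head of the biceps tendon.
ROI_NAMES = {1: "I", 2: "II", 3: "III", 4: "IV"}

COHORT_COLUMNS = ("specimen_id", "roi", "count", "object_area_px2", "other_tissue_area_px2")

# Palette for indexed ROI PNGs: 0 background, 1-4 distinguishable colours.
_ROI_PALETTE = {0: (0, 0, 0), 1: (230, 60, 60), 2: (60, 180, 75), 3: (60, 100, 230), 4: (240, 180, 40)}


class UnsupportedFormatError(ValueError):
    """Raised for image inputs that are not 8-bit RGB."""


class CohortTableError(ValueError):
    """Raised for malformed cohort-table files; message carries line numbers."""


@dataclasses.dataclass
class SlideMetadata:
    specimen_id: str = "unknown"
    side: str = "unknown"  # left | right
    sex: str = "unknown"  # f | m
    age: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SlideMetadata":
        return cls(**{k: d[k] for k in ("specimen_id", "side", "sex", "age") if k in d})


@dataclasses.dataclass
class Slide:
    """A full-resolution 8-bit RGB scan of a stained section."""

    pixels: np.ndarray
    metadata: SlideMetadata = dataclasses.field(default_factory=SlideMetadata)

    def __post_init__(self) -> None:
        _validate_rgb8(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclasses.dataclass
class ROIAnnotation:
    """Label mask over a slide: 0 = unassigned, 1-4 = ROI I-IV."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("ROI annotation must be a 2-D label mask")
        bad = np.setdiff1d(np.unique(labels), [0, 1, 2, 3, 4])
        if bad.size:
            raise ValueError(f"ROI annotation contains invalid labels: {bad.tolist()}")
        self.labels = labels.astype(np.uint8)

    def roi_mask(self, label: int) -> np.ndarray:
        if label not in ROI_LABELS:
            raise ValueError(f"ROI label must be one of {ROI_LABELS}, got {label}")
        return self.labels == label

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _validate_rgb8(arr: np.ndarray) -> None:
    if not isinstance(arr, np.ndarray):
        raise UnsupportedFormatError("pixel data must be a numpy array")
    if arr.dtype != np.uint8:
        raise UnsupportedFormatError(f"only 8-bit images are supported, got dtype {arr.dtype}")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise UnsupportedFormatError(f"only RGB images are supported, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise UnsupportedFormatError("image must have at least one row and one column")


def read_slide(path: str | Path, metadata: SlideMetadata | None = None) -> Slide:
    """Read an 8-bit RGB slide from TIFF or PNG.

    A JSON sidecar ``<path>.json`` with specimen metadata is picked up
    automatically when present and no explicit metadata is given.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    _validate_rgb8(arr)
    if metadata is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            metadata = SlideMetadata.from_dict(json.loads(sidecar.read_text()))
    return Slide(pixels=arr, metadata=metadata or SlideMetadata())


def write_slide(slide: Slide, path: str | Path, sidecar: bool = True) -> Path:
    """Write a slide as uncompressed 8-bit RGB TIFF (or PNG by extension)."""
    path = Path(path)
    _validate_rgb8(slide.pixels)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, slide.pixels, photometric="rgb", compression=None)
    else:
        Image.fromarray(slide.pixels, mode="RGB").save(path)
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(slide.metadata.to_dict(), indent=1)
        )
    return path


def read_roi_annotation(path: str | Path, slide_shape: tuple[int, int]) -> ROIAnnotation:
    """Read an indexed-PNG ROI mask and validate it against the slide shape."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise UnsupportedFormatError("ROI annotation must be a single-channel indexed image")
    if arr.shape != tuple(slide_shape):
        raise ValueError(
            f"ROI annotation shape {arr.shape} does not match slide shape {tuple(slide_shape)}"
        )
    return ROIAnnotation(labels=arr)


def write_roi_annotation(annotation: ROIAnnotation, path: str | Path) -> Path:
    path = Path(path)
    im = Image.fromarray(annotation.labels, mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    for k, rgb in _ROI_PALETTE.items():
        palette[k] = rgb
    im.putpalette(palette.ravel().tolist())
    im.save(path)
    return path


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG (0/255) for visual inspection."""
    path = Path(path)
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255))).save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 0


def validate_cohort_table(table: pd.DataFrame, integer_counts: bool = True) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortTableError(f"cohort table missing columns: {missing}")
    out = table.loc[:, list(COHORT_COLUMNS)].copy()
    if not set(out["roi"].unique()) <= set(ROI_LABELS):
        raise CohortTableError("roi column must contain labels 1-4")
    for col in ("count", "object_area_px2", "other_tissue_area_px2"):
        if (out[col] < 0).any():
            raise CohortTableError(f"negative values in column {col}")
    if integer_counts and not np.allclose(out["count"], np.round(out["count"])):
        raise CohortTableError("count column must be integer-valued")
    return out


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table as CSV with the canonical header."""
    path = Path(path)
    out = table.loc[:, list(COHORT_COLUMNS)] if len(table) else pd.DataFrame(columns=COHORT_COLUMNS)
    out.to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path, integer_counts: bool = True) -> pd.DataFrame:
    """Read a cohort-table CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortTableError(f"{path}: missing columns {missing}")
    converted = {}
    bad_lines: set[int] = set()
    for col in COHORT_COLUMNS:
        if col == "specimen_id":
            converted[col] = raw[col]
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        # +2: one for the header row, one for 1-based line numbering
        bad_lines.update((np.flatnonzero(vals.isna()) + 2).tolist())
        converted[col] = vals
    if bad_lines:
        raise CohortTableError(f"{path}: malformed rows at lines {sorted(bad_lines)}")
    table = pd.DataFrame(converted)
    table["roi"] = table["roi"].astype(int)
    if integer_counts:
        table["count"] = table["count"].astype(int)
    return validate_cohort_table(table, integer_counts=integer_counts)


def cohort_to_wide(table: pd.DataFrame, value: str = "count") -> pd.DataFrame:
    """Pivot a long cohort table to specimens x ROI-labels."""
    wide = table.pivot(index="specimen_id", columns="roi", values=value)
    return wide.reindex(columns=list(ROI_LABELS))


def groups_by_roi(table: pd.DataFrame, value: str = "count") -> dict[int, np.ndarray]:
    """Per-ROI value vectors, keyed by ROI label, in specimen order."""
    return {
        int(roi): sub[value].to_numpy(dtype=float)
        for roi, sub in table.groupby("roi", sort=True)
    }
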