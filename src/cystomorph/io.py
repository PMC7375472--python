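"""File-format plumbing: multi-page TIFF fields, label masks, structure CSVs,
YAML/JSON configs.

A field image is stored as a 3-page TIFF (bright-field, red, green) with a
JSON ImageDescription carrying ``pixel_size_um`` and ``timepoint_h``, so
real microscope exports (TIFF + pixel size) can enter the pipeline at the
segmentation stage.  Per-channel PNG export is available for quick looks.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .segment import StructureRecord
from .simulate import FieldImage

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_field_pngs",
    "write_label_tiff",
    "read_label_tiff",
    "records_to_frame",
    "write_records_csv",
    "load_config",
    "dump_config",
]

_CHANNELS = ("brightfield", "red", "green")


def write_field_tiff(image: FieldImage, path: str | Path) -> Path:
    """Write a field as a 3-page TIFF (BF, red, green) with calibration."""
    path = Path(path)
    stack = np.stack([image.brightfield, image.red, image.green])
    meta = {
        "pixel_size_um": image.pixel_size_um,
        "timepoint_h": image.timepoint_h,
        "channels": list(_CHANNELS),
    }
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=json.dumps(meta)
    )
    return path


def read_field_tiff(path: str | Path) -> FieldImage:
    """Read a field image written by :func:`write_field_tiff`."""
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"{path}: expected a 3-page (BF, red, green) TIFF")
    return FieldImage(
        brightfield=stack[0],
        red=stack[1],
        green=stack[2],
        pixel_size_um=float(meta["pixel_size_um"]),
        timepoint_h=float(meta.get("timepoint_h", 0.0)),
    )


def write_field_pngs(image: FieldImage, stem: str | Path) -> list[Path]:
    """Write one 16-bit PNG per channel as ``<stem>_<channel>.png``."""
    stem = Path(stem)
    paths = []
    for name in _CHANNELS:
        p = stem.parent / f"{stem.name}_{name}.png"
        iio.imwrite(p, getattr(image, name))
        paths.append(p)
    return paths


def write_label_tiff(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.int32))
    return path


def read_label_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def records_to_frame(records: list[StructureRecord]) -> pd.DataFrame:
    """Flatten structure records (without pixel masks) into a tidy table."""
    rows = []
    for r in records:
        rows.append(
            {
                "structure_id": r.structure_id,
                "field_id": r.field_id,
                "timepoint_h": r.timepoint_h,
                "width_um": r.width_um,
                "height_um": r.height_um,
                "area_um2": r.area_um2,
                "lumen_area_um2": r.lumen_area_um2,
                "centroid_x_um": r.centroid_um[0],
                "centroid_y_um": r.centroid_um[1],
                "border_clipped": r.border_clipped,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def write_records_csv(records: list[StructureRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def dump_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
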