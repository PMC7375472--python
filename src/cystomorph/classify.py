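"""Rule-based structure classification.

Operationalizes the descriptive bright-field criteria for tubuloid cultures:
prestructures are globular and lumen-less; spheroids show a circular clear
lumen; tubules a slit-like lumen with a diameter of roughly 50 μm.  The
rules fire in a fixed order on quantitative descriptors (lumen area
fraction, lumen circularity, bounding-box aspect ratio, minimum bounding
dimension), with an explicit ``ambiguous`` reject class for shapes that
satisfy none of them.  All cutoffs live in :class:`ClassifierThresholds`
and are reported alongside every call.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .segment import StructureRecord

__all__ = [
    "ClassifierThresholds",
    "StructureClassCall",
    "classify_structure",
    "classify_population",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric cutoffs behind the class rules (declared defaults)."""

    lumen_fraction_min: float = 0.05
    lumen_circularity_min: float = 0.6
    spheroid_aspect_max: float = 1.5
    tubule_aspect_min: float = 2.0
    tubule_width_band_um: tuple[float, float] = (30.0, 80.0)


DEFAULT_THRESHOLDS = ClassifierThresholds()


@dataclass(frozen=True)
class StructureClassCall:
    """Class label plus the descriptor values that produced it."""

    structure_id: int
    label: str
    aspect_ratio: float
    lumen_area_fraction: float
    lumen_circularity: float
    min_dimension_um: float
    rule_fired: str


def _largest_lumen_circularity(lumen_mask: np.ndarray) -> float:
    """Circularity ``4πA/P²`` of the largest connected lumen component.

    Crofton perimeters keep rasterization bias small; the value is clamped
    to 1.1 to absorb residual raster error on tiny lumens.
    """
    labels, n = ndi.label(lumen_mask)
    if n == 0:
        return 0.0
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    perim = measure.perimeter_crofton(labels == largest.label, directions=4)
    if perim <= 0:
        return 0.0
    return float(min(1.1, 4.0 * np.pi * largest.area / perim**2))


def classify_structure(
    record: StructureRecord,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> StructureClassCall:
    """Assign one structure to {prestructure, spheroid, tubule, ambiguous}.

    Decision order (first match wins):

    1. lumen area fraction < ``lumen_fraction_min`` → ``prestructure``
    2. lumen present, circular (≥ ``lumen_circularity_min``) and compact
       bounding box (aspect ≤ ``spheroid_aspect_max``) → ``spheroid``
    3. lumen present, elongated (aspect ≥ ``tubule_aspect_min``) with the
       minimum bounding dimension inside the tubule diameter band →
       ``tubule``
    4. otherwise → ``ambiguous``
    """
    if record.mask is not None and record.lumen_mask is None:
        raise ValueError("record lacks a lumen computation; segment first")
    aspect = max(record.width_um, record.height_um) / min(
        record.width_um, record.height_um
    )
    min_dim = min(record.width_um, record.height_um)
    if record.area_um2 <= 0:
        raise ValueError("record has non-positive area")
    lumen_frac = record.lumen_area_um2 / record.area_um2
    circ = (
        _largest_lumen_circularity(record.lumen_mask)
        if record.lumen_mask is not None
        else float(record.extra.get("lumen_circularity", 0.0))
    )
    lo, hi = thresholds.tubule_width_band_um
    if lumen_frac < thresholds.lumen_fraction_min:
        label, rule = "prestructure", "no_lumen"
    elif circ >= thresholds.lumen_circularity_min and aspect <= thresholds.spheroid_aspect_max:
        label, rule = "spheroid", "circular_lumen_compact"
    elif aspect >= thresholds.tubule_aspect_min and lo <= min_dim <= hi:
        label, rule = "tubule", "slit_lumen_elongated"
    else:
        label, rule = "ambiguous", "no_rule"
    return StructureClassCall(
        structure_id=record.structure_id,
        label=label,
        aspect_ratio=float(aspect),
        lumen_area_fraction=float(lumen_frac),
        lumen_circularity=circ,
        min_dimension_um=float(min_dim),
        rule_fired=rule,
    )


def classify_population(
    records: list[StructureRecord],
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Class-count table per field/replicate.

    Expects records that already passed the exclusion rules.  Returns one
    row per ``field_id`` with per-class counts, per-class fractions (summing
    to 1 within a replicate), and the derived ``differentiated_fraction``
    (spheroids + tubules) and ``tubule_of_total_fraction``.
    """
    if not records:
        return pd.DataFrame(
            columns=["field_id", "n_total"]
        )
    rows = []
    for rec in records:
        call = classify_structure(rec, thresholds)
        rows.append({"field_id": rec.field_id, "label": call.label})
    df = pd.DataFrame(rows)
    classes = ["prestructure", "spheroid", "tubule", "ambiguous"]
    out = []
    for fid, grp in df.groupby("field_id", sort=True):
        counts = {c: int((grp["label"] == c).sum()) for c in classes}
        n = len(grp)
        row: dict = {"field_id": fid, "n_total": n}
        row.update({f"n_{c}": counts[c] for c in classes})
        row.update({f"frac_{c}": counts[c] / n for c in classes})
        row["differentiated_fraction"] = (counts["spheroid"] + counts["tubule"]) / n
        row["tubule_of_total_fraction"] = counts["tubule"] / n
        out.append(row)
    result = pd.DataFrame(out)
    result.attrs["thresholds"] = asdict(thresholds)
    return result
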