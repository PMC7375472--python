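"""Spherical-agreement morphometry.

A structure's likeness to a sphere (cyst) is scored on a bounded 0–1 scale
from the three region statistics an imaging package reports for a drawn ROI:
bounding-box width ``w``, height ``h`` and area ``A`` (all in μm / μm²).

The score compares the measured area with a *spherical-like* reference area
built from the shortest bounding-box dimension:

``normalized`` convention (default)
    reference disk of diameter ``min(w, h)``: ``r = min(w, h)/2``,
    ``A_s = π r²``.  Agreement ``S = max(0, 1 − |A − A_s| / A_s)`` — exactly 1
    for a disk, decreasing with elongation, clamped at 0 for strongly
    tubule-like shapes.  This is the unique simple reading that places the
    scale's stated endpoints (1 = spheroid, 0 = tubule) correctly.

``as_printed`` convention
    the literal recipe some lab protocols print, ``r = min(w, h)`` and
    ``A_s = 2π r²``; kept behind a flag for transparency.  Its reference area
    is 8× the inscribed disk, so a perfect disk does not score 1; the score is
    still clamped to [0, 1].

The percent difference is relative to the reference area by default; dividing
by the measured area instead is available via ``denominator="measured"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MorphoScore",
    "spherical_like_area",
    "spherical_agreement",
    "agreement_delta",
]

_CONVENTIONS = ("normalized", "as_printed")


@dataclass(frozen=True)
class MorphoScore:
    """Spherical-agreement result for one structure at one timepoint."""

    r_um: float
    spherical_like_area_um2: float
    percent_difference: float
    agreement: float
    convention: str


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {_CONVENTIONS}")


def spherical_like_area(
    width_um: float, height_um: float, convention: str = "normalized"
) -> tuple[float, float]:
    """Radius and spherical-like reference area from bounding-box dimensions.

    Returns ``(r_um, A_s_um2)``.  The shortest of width/height defines the
    radius: as the diameter of the reference disk under ``normalized``
    (``r = min/2``, ``A_s = πr²``), or taken directly as ``r`` with
    ``A_s = 2πr²`` under ``as_printed``.
    """
    _check_convention(convention)
    if width_um <= 0 or height_um <= 0:
        raise ValueError("width and height must be positive")
    shortest = min(width_um, height_um)
    if convention == "normalized":
        r = shortest / 2.0
        return r, np.pi * r * r
    r = shortest
    return r, 2.0 * np.pi * r * r


def spherical_agreement(
    width_um: float,
    height_um: float,
    area_um2: float,
    convention: str = "normalized",
    denominator: str = "reference",
) -> MorphoScore:
    """Score a structure's sphere-likeness on the bounded [0, 1] scale.

    Parameters
    ----------
    width_um, height_um
        Axis-aligned bounding-box extent of the structure (μm).
    area_um2
        Measured structure area (μm²); must not exceed ``w*h``.
    convention
        ``"normalized"`` (default) or ``"as_printed"``; see module docstring.
    denominator
        ``"reference"`` divides the area difference by the spherical-like
        area ``A_s``; ``"measured"`` divides by the measured area.

    Returns
    -------
    MorphoScore
        with ``agreement`` in [0, 1]: 1 = spheroid/cyst-like, 0 = tubule-like.
    """
    if denominator not in ("reference", "measured"):
        raise ValueError("denominator must be 'reference' or 'measured'")
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if area_um2 > width_um * height_um * (1.0 + 1e-9):
        raise ValueError(
            f"area {area_um2} exceeds bounding box {width_um}x{height_um}"
        )
    r, a_s = spherical_like_area(width_um, height_um, convention)
    denom = a_s if denominator == "reference" else area_um2
    d = abs(area_um2 - a_s) / denom
    s = min(1.0, max(0.0, 1.0 - d))
    return MorphoScore(
        r_um=r,
        spherical_like_area_um2=a_s,
        percent_difference=d,
        agreement=s,
        convention=convention,
    )


def agreement_delta(before: MorphoScore, after: MorphoScore) -> float:
    """Signed change in agreement, ``S_after − S_before``.

    Positive values mean the structure became more cyst-like.  Both scores
    must have been computed under the same convention.
    """
    if before.convention != after.convention:
        raise ValueError(
            f"mixed conventions: {before.convention!r} vs {after.convention!r}"
        )
    return after.agreement - before.agreement
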