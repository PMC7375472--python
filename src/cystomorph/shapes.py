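"""Analytic capsule (stadium) geometry.

Every simulated structure is a 2-D capsule: a rectangle of length
``length - width`` capped by two semicircles of diameter ``width``.  At
``length == width`` the capsule degenerates continuously to a disk, so one
parameterization covers globular prestructures, circular spheroids and
elongated tubules.  The lumen is an inner capsule at uniform wall
thickness: lumen width ``f*width`` and lumen length ``length - width*(1-f)``
for lumen fraction ``f``, which reduces to a concentric disk for spheroids
and to a slit for tubules.

These closed forms are shared by the simulator (ground truth) and by the
test oracles that check rasterized measurements against analytic values.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "capsule_area",
    "lumen_dimensions",
    "lumen_area",
    "net_area",
    "bounding_box",
    "rasterize_capsule",
]


def capsule_area(width_um: float, length_um: float) -> float:
    """Filled area of a capsule, ``w*(L-w) + pi*(w/2)**2`` (μm²)."""
    if width_um <= 0 or length_um < width_um:
        raise ValueError(
            f"capsule requires length >= width > 0, got w={width_um}, L={length_um}"
        )
    return width_um * (length_um - width_um) + np.pi * (width_um / 2.0) ** 2


def lumen_dimensions(
    width_um: float, length_um: float, lumen_fraction: float
) -> tuple[float, float]:
    """(width, length) of the inner lumen capsule; (0, 0) when there is no lumen.

    The lumen sits at uniform wall thickness ``w*(1-f)/2`` all around, so its
    centerline coincides with the structure's centerline.
    """
    if not 0.0 <= lumen_fraction < 0.9:
        raise ValueError(f"lumen_fraction must be in [0, 0.9), got {lumen_fraction}")
    if lumen_fraction == 0.0:
        return 0.0, 0.0
    lw = lumen_fraction * width_um
    ll = length_um - width_um * (1.0 - lumen_fraction)
    return lw, ll


def lumen_area(width_um: float, length_um: float, lumen_fraction: float) -> float:
    """Area of the lumen capsule (μm²); 0 for lumen-less structures."""
    lw, ll = lumen_dimensions(width_um, length_um, lumen_fraction)
    if lw == 0.0:
        return 0.0
    return capsule_area(lw, ll)


def net_area(width_um: float, length_um: float, lumen_fraction: float) -> float:
    """Structure area excluding the lumen (μm²) — what a segmented mask measures."""
    return capsule_area(width_um, length_um) - lumen_area(
        width_um, length_um, lumen_fraction
    )


def bounding_box(
    width_um: float, length_um: float, orientation_rad: float
) -> tuple[float, float]:
    """Axis-aligned bounding-box (extent_x, extent_y) of a rotated capsule.

    The capsule is the Minkowski sum of a segment of length ``L - w`` and a
    disk of diameter ``w``; its support width along an axis is therefore
    ``(L - w)*|cos θ| + w`` (x) and ``(L - w)*|sin θ| + w`` (y).
    """
    d = length_um - width_um
    ex = d * abs(np.cos(orientation_rad)) + width_um
    ey = d * abs(np.sin(orientation_rad)) + width_um
    return ex, ey


def _segment_distance_field(
    shape_px: tuple[int, int],
    centroid_um: tuple[float, float],
    length_um: float,
    width_um: float,
    orientation_rad: float,
    pixel_size_um: float,
    window: tuple[slice, slice] | None = None,
) -> np.ndarray:
    """Distance (μm) from pixel centers to the capsule's central segment."""
    rows = np.arange(shape_px[0]) if window is None else np.arange(
        window[0].start, window[0].stop
    )
    cols = np.arange(shape_px[1]) if window is None else np.arange(
        window[1].start, window[1].stop
    )
    # pixel (r, c) center at x=(c+0.5)*px, y=(r+0.5)*px
    y = (rows[:, None] + 0.5) * pixel_size_um - centroid_um[1]
    x = (cols[None, :] + 0.5) * pixel_size_um - centroid_um[0]
    half = (length_um - width_um) / 2.0
    ux, uy = np.cos(orientation_rad), np.sin(orientation_rad)
    # projection of each pixel onto the segment axis, clamped to the segment
    t = np.clip(x * ux + y * uy, -half, half)
    dx = x - t * ux
    dy = y - t * uy
    return np.hypot(dx, dy)


def rasterize_capsule(
    shape_px: tuple[int, int],
    centroid_um: tuple[float, float],
    width_um: float,
    length_um: float,
    lumen_fraction: float,
    orientation_rad: float,
    pixel_size_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a capsule onto a pixel grid.

    Returns
    -------
    mask, lumen : bool arrays of shape ``shape_px``
        ``mask`` covers structure pixels excluding the lumen; ``lumen`` covers
        the enclosed lumen pixels.  A pixel belongs to a region when its
        center falls inside the analytic shape.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    # restrict work to the bounding window (+1 px margin)
    ex, ey = bounding_box(width_um, length_um, orientation_rad)
    r0 = max(0, int((centroid_um[1] - ey / 2) / pixel_size_um) - 1)
    r1 = min(shape_px[0], int((centroid_um[1] + ey / 2) / pixel_size_um) + 2)
    c0 = max(0, int((centroid_um[0] - ex / 2) / pixel_size_um) - 1)
    c1 = min(shape_px[1], int((centroid_um[0] + ex / 2) / pixel_size_um) + 2)
    mask = np.zeros(shape_px, dtype=bool)
    lumen = np.zeros(shape_px, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask, lumen
    window = (slice(r0, r1), slice(c0, c1))
    dist = _segment_distance_field(
        shape_px, centroid_um, length_um, width_um, orientation_rad,
        pixel_size_um, window,
    )
    inside = dist <= width_um / 2.0
    in_lumen = dist <= lumen_fraction * width_um / 2.0
    mask[window] = inside & ~in_lumen
    lumen[window] = in_lumen
    return mask, lumen
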