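"""Synthetic tubuloid field generator with ground truth.

Emulates the imaging design of a 3-D tubuloid cystogenesis assay: fields of
view containing lumen-less globular *prestructures*, *spheroids* with a
circular clear lumen, and *tubules* with a slit-like lumen roughly 50 μm in
diameter; two magnification regimes (population overviews at ~1.6 μm/px,
individual tracking at ~0.32 μm/px); a doxycycline-induced mosaic red→green
reporter conversion restricted to differentiated (epithelial) structures;
and a post-induction morphological drift of converted tubules toward
spheres over a 168 h time course.

All structures are analytic capsules (see :mod:`cystomorph.shapes`), so
every downstream measurement can be checked against closed-form truth.
Bright-field is rendered as a bright-object-on-dark proxy (lumen at
background intensity, creating an enclosed hole) rather than true
transmitted-light texture — a deliberate simplification that keeps
segmentation deterministic and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import morphometry, shapes
from .segment import StructureRecord

__all__ = [
    "CLASSES",
    "DIFFERENTIATED",
    "PIXEL_SIZE_POPULATION_UM",
    "PIXEL_SIZE_INDIVIDUAL_UM",
    "ShapeParams",
    "ClassPrior",
    "PopulationPriors",
    "TimeCourseConfig",
    "SimulatedTruth",
    "FieldImage",
    "generate_structure",
    "simulate_timecourse",
    "render_field",
    "sample_positions",
    "population_scenario",
    "tracked_scenario",
    "truth_table",
    "truth_records",
]

CLASSES = ("prestructure", "spheroid", "tubule")
DIFFERENTIATED = ("spheroid", "tubule")

#: default μm-per-pixel calibrations for the two magnification regimes
PIXEL_SIZE_POPULATION_UM = 1.6   # 4x objective, population overviews
PIXEL_SIZE_INDIVIDUAL_UM = 0.32  # 20x objective, individual tracking


@dataclass
class ShapeParams:
    """Geometry of one capsule structure at one timepoint.

    ``width_um`` is the minor (cap) dimension, ``length_um`` the major one
    (equal for disks); ``lumen_fraction`` scales the inner lumen capsule
    (0 = no lumen); ``orientation_rad`` rotates the capsule in-plane;
    ``centroid_um`` places it in field coordinates (x, y).
    """

    kind: str
    width_um: float
    length_um: float
    lumen_fraction: float
    orientation_rad: float = 0.0
    centroid_um: tuple[float, float] = (0.0, 0.0)
    defocus_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in CLASSES:
            raise ValueError(f"unknown structure class {self.kind!r}")
        if not self.length_um >= self.width_um > 0:
            raise ValueError("requires length_um >= width_um > 0")
        if not 0.0 <= self.lumen_fraction < 0.9:
            raise ValueError("lumen_fraction must lie in [0, 0.9)")
        if self.kind == "prestructure" and self.lumen_fraction != 0.0:
            raise ValueError("prestructures are lumen-less")

    @property
    def elongation(self) -> float:
        return self.length_um / self.width_um

    def bbox_um(self) -> tuple[float, float]:
        return shapes.bounding_box(self.width_um, self.length_um, self.orientation_rad)

    def net_area_um2(self) -> float:
        return shapes.net_area(self.width_um, self.length_um, self.lumen_fraction)


@dataclass(frozen=True)
class ClassPrior:
    """Uniform sampling bands for one structure class."""

    width_um: tuple[float, float]
    aspect: tuple[float, float]
    lumen_fraction: tuple[float, float]


@dataclass(frozen=True)
class PopulationPriors:
    """Per-class shape priors plus the common orientation prior.

    Orientations are near-axis-aligned (sd 0.05 rad about a random field
    axis): descriptors downstream are axis-aligned bounding boxes, and the
    generator emulates cultures whose tubule fragments settle along the gel
    spreading direction.
    """

    prestructure: ClassPrior = ClassPrior((40, 90), (1.0, 1.4), (0.0, 0.0))
    spheroid: ClassPrior = ClassPrior((60, 120), (1.0, 1.2), (0.4, 0.7))
    tubule: ClassPrior = ClassPrior((35, 60), (2.5, 3.5), (0.2, 0.4))
    orientation_sd_rad: float = 0.05

    def for_class(self, kind: str) -> ClassPrior:
        return getattr(self, kind)


DEFAULT_PRIORS = PopulationPriors()

#: prior for individually tracked tubules in the cystogenesis assay:
#: moderately elongated tubules whose baseline agreement score lies in the
#: interior of the 0-1 scale (saturated score-0 structures carry no paired
#: information)
TRACKED_TUBULE_PRIOR = ClassPrior((40, 65), (2.0, 2.15), (0.35, 0.45))


@dataclass
class TimeCourseConfig:
    """Imaging schedule, treatment arm and dynamics of one scenario.

    ``relaxation_rate_per_h`` is the exponential rate λ at which a converted
    structure's elongation decays toward 1 (disk);
    ``conversion_prob`` the chance a differentiated structure converts
    (Cre fires) in the doxycycline arm; ``mosaic_green_fraction`` the
    per-structure fraction of converted (green) pixels; ``jitter_sd`` the
    multiplicative log-normal geometric noise per timepoint; ``drift_sd_um``
    the per-timepoint centroid random-walk step.
    """

    timepoints_h: tuple[float, ...] = (0.0, 48.0, 96.0, 168.0)
    induction_time_h: float = 0.0
    arm: str = "doxycycline"
    relaxation_rate_per_h: float = 0.008
    conversion_prob: float = 0.8
    mosaic_green_fraction: float = 0.8
    jitter_sd: float = 0.03
    drift_sd_um: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("doxycycline", "control"):
            raise ValueError(f"arm must be 'doxycycline' or 'control', got {self.arm!r}")
        tp = tuple(float(t) for t in self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_h must be strictly increasing")
        self.timepoints_h = tp
        if self.relaxation_rate_per_h < 0:
            raise ValueError("relaxation_rate_per_h must be >= 0")
        for name in ("conversion_prob", "mosaic_green_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.arm == "control":
            self.conversion_prob = 0.0


@dataclass
class SimulatedTruth:
    """Ground truth for one structure: class, conversion and per-timepoint geometry."""

    structure_id: int
    kind: str
    baseline: ShapeParams
    converted: bool = False
    mosaic_green_fraction: float = 0.0
    shapes: dict[float, ShapeParams] = field(default_factory=dict)

    def shape_at(self, timepoint_h: float) -> ShapeParams:
        try:
            return self.shapes[timepoint_h]
        except KeyError:
            raise KeyError(
                f"structure {self.structure_id} has no geometry at t={timepoint_h}"
            ) from None

    def bbox_um(self, timepoint_h: float) -> tuple[float, float]:
        return self.shape_at(timepoint_h).bbox_um()

    def area_um2(self, timepoint_h: float) -> float:
        return self.shape_at(timepoint_h).net_area_um2()

    def agreement(self, timepoint_h: float, convention: str = "normalized") -> float:
        """Analytic spherical-agreement score from true bbox and net area."""
        bw, bh = self.bbox_um(timepoint_h)
        return morphometry.spherical_agreement(
            bw, bh, self.area_um2(timepoint_h), convention=convention
        ).agreement

    def border_clipped(self, timepoint_h: float, field_size_um: float) -> bool:
        sp = self.shape_at(timepoint_h)
        bw, bh = sp.bbox_um()
        cx, cy = sp.centroid_um
        return (
            cx - bw / 2 < 0
            or cy - bh / 2 < 0
            or cx + bw / 2 > field_size_um
            or cy + bh / 2 > field_size_um
        )


@dataclass
class FieldImage:
    """One multi-channel field of view at one timepoint."""

    brightfield: np.ndarray
    red: np.ndarray
    green: np.ndarray
    pixel_size_um: float
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (self.brightfield.shape == self.red.shape == self.green.shape):
            raise ValueError("all channels must share one shape")


def _sample_band(rng: np.random.Generator, band: tuple[float, float]) -> float:
    lo, hi = band
    return lo if lo == hi else float(rng.uniform(lo, hi))


def generate_structure(
    kind: str,
    rng: np.random.Generator,
    priors: PopulationPriors = DEFAULT_PRIORS,
    centroid_um: tuple[float, float] = (0.0, 0.0),
    prior: ClassPrior | None = None,
    structure_id: int = 0,
) -> tuple[ShapeParams, SimulatedTruth]:
    """Draw one structure of the given class from the population priors.

    Class-specific shape bands (spheroid elongation ≤ 1.2; tubule elongation
    ≥ 2 with width in 30–80 μm; prestructure lumen-less) are enforced here,
    at generation time; later morphological relaxation may leave them.
    """
    if kind not in CLASSES:
        raise ValueError(f"unknown structure class {kind!r}")
    band = prior if prior is not None else priors.for_class(kind)
    width = _sample_band(rng, band.width_um)
    aspect = _sample_band(rng, band.aspect)
    lumen = _sample_band(rng, band.lumen_fraction)
    if kind == "prestructure":
        lumen = 0.0
    axis = rng.integers(0, 2) * (math.pi / 2.0)
    theta = float(axis + rng.normal(0.0, priors.orientation_sd_rad))
    sp = ShapeParams(
        kind=kind,
        width_um=width,
        length_um=width * aspect,
        lumen_fraction=lumen,
        orientation_rad=theta,
        centroid_um=centroid_um,
    )
    if kind == "spheroid":
        assert sp.elongation <= 1.2 + 1e-9
    if kind == "tubule":
        assert sp.elongation >= 2.0 - 1e-9 and 30.0 <= sp.width_um <= 80.0
    truth = SimulatedTruth(structure_id=structure_id, kind=kind, baseline=sp)
    return sp, truth


def simulate_timecourse(
    structures: list[SimulatedTruth],
    tc: TimeCourseConfig,
    rng: np.random.Generator,
) -> list[SimulatedTruth]:
    """Fill per-timepoint geometry for every structure (in place; also returned).

    Conversion: in the doxycycline arm each *differentiated* structure
    converts with probability ``conversion_prob``; prestructures never
    convert.  Converted structures relax their elongation as
    ``E(t) = 1 + (E0 - 1) * exp(-λ (t - t_induction))`` for ``t ≥ t_induction``
    (width preserved, length shrinking), on top of multiplicative log-normal
    jitter applied to width and length at every timepoint.  Non-converted
    and control structures keep baseline elongation up to jitter.  Centroids
    random-walk with per-timepoint step ``drift_sd_um``.
    """
    if not structures:
        raise ValueError("structure list must not be empty")
    tp = tc.timepoints_h
    t0 = tc.induction_time_h
    if not any(t <= t0 for t in tp) or not any(t >= t0 + 96.0 for t in tp):
        raise ValueError(
            "time course needs >=1 timepoint before induction and one >=96 h after"
        )
    draws = rng.random(len(structures))
    for truth, u in zip(structures, draws):
        if truth.kind in DIFFERENTIATED and u < tc.conversion_prob:
            truth.converted = True
            truth.mosaic_green_fraction = tc.mosaic_green_fraction
        else:
            truth.converted = False
            truth.mosaic_green_fraction = 0.0
    lam = tc.relaxation_rate_per_h
    for truth in structures:
        base = truth.baseline
        e0 = base.elongation
        cx, cy = base.centroid_um
        truth.shapes = {}
        for i, t in enumerate(tp):
            if truth.converted and t >= t0:
                e = 1.0 + (e0 - 1.0) * math.exp(-lam * (t - t0))
            else:
                e = e0
            if tc.jitter_sd > 0:
                jw = float(rng.lognormal(0.0, tc.jitter_sd))
                jl = float(rng.lognormal(0.0, tc.jitter_sd))
            else:
                jw = jl = 1.0
            if i > 0 and tc.drift_sd_um > 0:
                cx += float(rng.normal(0.0, tc.drift_sd_um))
                cy += float(rng.normal(0.0, tc.drift_sd_um))
            w = base.width_um * jw
            length = max(w, base.width_um * e * jl)
            truth.shapes[t] = replace(
                base, width_um=w, length_um=length, centroid_um=(cx, cy)
            )
    return structures


def render_field(
    structures: list[SimulatedTruth],
    timepoint_h: float,
    field_size_um: float,
    pixel_size_um: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    induction_time_h: float = 0.0,
    bf_background: float = 2000.0,
    bf_foreground: float = 30000.0,
    fl_background: float = 500.0,
    fl_foreground: float = 20000.0,
) -> tuple[FieldImage, np.ndarray]:
    """Rasterize one timepoint of a scenario into a 3-channel field image.

    Bright-field shows each structure as a filled capsule of elevated
    intensity with the lumen left at background (an enclosed hole).  All
    structures express membrane tdTomato (red); converted structures show a
    mosaic of green pixels (per-pixel Bernoulli at the structure's
    ``mosaic_green_fraction``) from ``induction_time_h`` onward, the
    remaining pixels staying red.  The label mask carries the ground-truth
    ``structure_id`` per structure pixel.

    Additive Gaussian noise of standard deviation ``noise_sd`` (16-bit
    intensity units) is applied to all channels when ``rng`` is given.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    n_px = int(round(field_size_um / pixel_size_um))
    shape_px = (n_px, n_px)
    bf = np.full(shape_px, bf_background, dtype=float)
    red = np.full(shape_px, fl_background, dtype=float)
    green = np.full(shape_px, fl_background, dtype=float)
    labels = np.zeros(shape_px, dtype=np.int32)
    for truth in sorted(structures, key=lambda s: s.structure_id):
        sp = truth.shape_at(timepoint_h)
        mask, _lumen = shapes.rasterize_capsule(
            shape_px, sp.centroid_um, sp.width_um, sp.length_um,
            sp.lumen_fraction, sp.orientation_rad, pixel_size_um,
        )
        if not mask.any():
            continue
        if sp.defocus_sigma_px > 0:
            layer = np.zeros(shape_px, dtype=float)
            layer[mask] = 1.0
            layer = ndi.gaussian_filter(layer, sp.defocus_sigma_px)
            bf += (bf_foreground - bf_background) * layer
        else:
            bf[mask] = bf_foreground
        labels[mask] = truth.structure_id
        show_green = truth.converted and timepoint_h >= induction_time_h
        if show_green and truth.mosaic_green_fraction > 0:
            n_in = int(mask.sum())
            sel = (
                rng.random(n_in) < truth.mosaic_green_fraction
                if rng is not None
                else np.zeros(n_in, dtype=bool)
            )
            idx = np.flatnonzero(mask.ravel())
            red_flat = red.ravel()
            green_flat = green.ravel()
            green_flat[idx[sel]] = fl_foreground
            red_flat[idx[~sel]] = fl_foreground
        else:
            red[mask] = fl_foreground
    if noise_sd > 0 and rng is not None:
        bf += rng.normal(0.0, noise_sd, shape_px)
        red += rng.normal(0.0, noise_sd, shape_px)
        green += rng.normal(0.0, noise_sd, shape_px)
    to_u16 = lambda a: np.clip(a, 0, 65535).astype(np.uint16)  # noqa: E731
    img = FieldImage(
        brightfield=to_u16(bf),
        red=to_u16(red),
        green=to_u16(green),
        pixel_size_um=pixel_size_um,
        timepoint_h=timepoint_h,
    )
    return img, labels


def sample_positions(
    n: int,
    field_size_um: float,
    margin_um: float,
    rng: np.random.Generator,
    jitter_frac: float = 0.1,
) -> list[tuple[float, float]]:
    """Jittered-grid centroids keeping structures apart and off the border."""
    side = math.ceil(math.sqrt(n))
    span = field_size_um - 2 * margin_um
    if span <= 0:
        raise ValueError("field too small for requested margin")
    step = span / side
    positions = []
    for k in range(n):
        gx, gy = k % side, k // side
        x = margin_um + (gx + 0.5) * step + rng.uniform(-jitter_frac, jitter_frac) * step
        y = margin_um + (gy + 0.5) * step + rng.uniform(-jitter_frac, jitter_frac) * step
        positions.append((float(x), float(y)))
    return positions


def population_scenario(
    n_structures: int,
    rng: np.random.Generator,
    class_probs: dict[str, float] | None = None,
    field_size_um: float = 1536.0,
    priors: PopulationPriors = DEFAULT_PRIORS,
    timepoint_h: float = 0.0,
) -> list[SimulatedTruth]:
    """One snapshot field: a class mixture at a single timepoint.

    ``class_probs`` defaults to an even three-way mixture; raising the
    tubule weight emulates a GDNF-boosted culture.
    """
    if class_probs is None:
        class_probs = {c: 1.0 / 3.0 for c in CLASSES}
    names = list(class_probs)
    p = np.array([class_probs[c] for c in names], dtype=float)
    p = p / p.sum()
    margin = max(
        priors.for_class(c).width_um[1] * priors.for_class(c).aspect[1] for c in CLASSES
    ) / 2.0 + 10.0
    positions = sample_positions(n_structures, field_size_um, margin, rng)
    kinds = rng.choice(names, size=n_structures, p=p)
    truths = []
    for i, (kind, pos) in enumerate(zip(kinds, positions), start=1):
        _, truth = generate_structure(
            str(kind), rng, priors, centroid_um=pos, structure_id=i
        )
        truth.shapes[timepoint_h] = truth.baseline
        truths.append(truth)
    return truths


def tracked_scenario(
    tc: TimeCourseConfig,
    rng: np.random.Generator,
    n_structures: int = 20,
    field_size_um: float = 1536.0,
    prior: ClassPrior = TRACKED_TUBULE_PRIOR,
) -> list[SimulatedTruth]:
    """The individual-tracking cystogenesis assay: n differentiated tubules
    revisited at every timepoint of ``tc``, with conversion and relaxation
    dynamics applied."""
    margin = prior.width_um[1] * prior.aspect[1] / 2.0 + 25.0
    positions = sample_positions(n_structures, field_size_um, margin, rng)
    truths = []
    for i, pos in enumerate(positions, start=1):
        _, truth = generate_structure(
            "tubule", rng, prior=prior, centroid_um=pos, structure_id=i
        )
        truths.append(truth)
    return simulate_timecourse(truths, tc, rng)


def truth_table(
    structures: list[SimulatedTruth],
    field_size_um: float | None = None,
    convention: str = "normalized",
) -> pd.DataFrame:
    """Tidy ground-truth table: one row per structure per timepoint."""
    rows = []
    for truth in structures:
        for t, sp in sorted(truth.shapes.items()):
            bw, bh = sp.bbox_um()
            rows.append(
                {
                    "structure_id": truth.structure_id,
                    "timepoint_h": t,
                    "class": truth.kind,
                    "width_um": sp.width_um,
                    "length_um": sp.length_um,
                    "lumen_fraction": sp.lumen_fraction,
                    "orientation_rad": sp.orientation_rad,
                    "centroid_x_um": sp.centroid_um[0],
                    "centroid_y_um": sp.centroid_um[1],
                    "bbox_w_um": bw,
                    "bbox_h_um": bh,
                    "area_um2": sp.net_area_um2(),
                    "agreement": truth.agreement(t, convention),
                    "converted": truth.converted,
                    "border_clipped": (
                        truth.border_clipped(t, field_size_um)
                        if field_size_um is not None
                        else False
                    ),
                }
            )
    return pd.DataFrame(rows)


def truth_records(
    structures: list[SimulatedTruth],
    pixel_size_um: float = PIXEL_SIZE_POPULATION_UM,
    field_size_um: float | None = None,
) -> dict[float, list[StructureRecord]]:
    """Build mask-less StructureRecords directly from ground truth.

    Useful for exercising tracking and statistics at the truth level,
    without rendering and re-segmenting images.
    """
    out: dict[float, list[StructureRecord]] = {}
    for truth in structures:
        for t, sp in truth.shapes.items():
            bw, bh = sp.bbox_um()
            rec = StructureRecord(
                structure_id=truth.structure_id,
                timepoint_h=t,
                pixel_size_um=pixel_size_um,
                width_um=bw,
                height_um=bh,
                area_um2=sp.net_area_um2(),
                centroid_um=sp.centroid_um,
                border_clipped=(
                    truth.border_clipped(t, field_size_um)
                    if field_size_um is not None
                    else False
                ),
                extra={"true_class": truth.kind, "true_converted": truth.converted},
            )
            out.setdefault(t, []).append(rec)
    return {t: out[t] for t in sorted(out)}
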