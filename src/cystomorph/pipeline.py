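"""End-to-end assay pipeline: simulate → render → segment → exclude →
classify → track → quantify fluorescence → morphometry → statistics.

One :class:`PipelineConfig` fully determines a run; identical config and
seed reproduce byte-identical output bundles.  Every run writes its
resolved configuration and a manifest (config hash, seed, per-stage record
counts) beside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import ClassifierThresholds, classify_population, classify_structure
from .fluorescence import (
    DEFAULT_CONVERSION_CUTOFF,
    conversion_summary,
    count_color_pixels,
    estimate_channel_threshold,
)
from .morphometry import spherical_agreement
from .segment import (
    DEFAULT_FOCUS_THRESHOLD,
    DEFAULT_MIN_AREA_UM2,
    apply_exclusions,
    segment_brightfield,
)
from .simulate import (
    PIXEL_SIZE_POPULATION_UM,
    TimeCourseConfig,
    render_field,
    tracked_scenario,
)
from .stats import paired_agreement_analysis, two_sample_t_test
from .tracking import DEFAULT_GATE_UM, build_tracks

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

ARMS = ("doxycycline", "control")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Serializable parameters of one full assay run."""

    seed: int = 0
    n_structures_per_arm: int = 20
    timepoints_h: tuple[float, ...] = (0.0, 48.0, 96.0, 168.0)
    induction_time_h: float = 0.0
    relaxation_rate_per_h: float = 0.008
    conversion_prob: float = 0.8
    mosaic_green_fraction: float = 0.8
    jitter_sd: float = 0.03
    drift_sd_um: float = 5.0
    field_size_um: float = 1536.0
    pixel_size_um: float = PIXEL_SIZE_POPULATION_UM
    noise_sd: float = 300.0
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    focus_threshold: float = DEFAULT_FOCUS_THRESHOLD
    gate_um: float = DEFAULT_GATE_UM
    convention: str = "normalized"
    eval_time_h: float = 168.0
    conversion_cutoff: float = DEFAULT_CONVERSION_CUTOFF
    write_images: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size_um is None or self.pixel_size_um <= 0:
            raise ValueError("config requires a positive pixel_size_um")
        self.timepoints_h = tuple(float(t) for t in self.timepoints_h)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints_h"] = list(d["timepoints_h"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _run_arm(config: PipelineConfig, arm: str, arm_index: int, outdir: Path):
    """Simulate, render, segment and quantify one treatment arm."""
    tc = TimeCourseConfig(
        timepoints_h=config.timepoints_h,
        induction_time_h=config.induction_time_h,
        arm=arm,
        relaxation_rate_per_h=config.relaxation_rate_per_h,
        conversion_prob=config.conversion_prob,
        mosaic_green_fraction=config.mosaic_green_fraction,
        jitter_sd=config.jitter_sd,
        drift_sd_um=config.drift_sd_um,
    )
    rng = np.random.default_rng([config.seed % (2**31), arm_index])
    truths = tracked_scenario(
        tc, rng, n_structures=config.n_structures_per_arm,
        field_size_um=config.field_size_um,
    )
    records_by_time: dict[float, list] = {}
    counts = {"segmented": 0, "excluded": 0}
    for t in config.timepoints_h:
        img, labels = render_field(
            truths, t, config.field_size_um, config.pixel_size_um,
            noise_sd=config.noise_sd, rng=rng,
            induction_time_h=config.induction_time_h,
        )
        if config.write_images:
            imgdir = outdir / "images"
            imgdir.mkdir(exist_ok=True)
            io.write_field_tiff(img, imgdir / f"{arm}_t{int(t):03d}.tiff")
            io.write_label_tiff(labels, imgdir / f"{arm}_t{int(t):03d}_labels.tiff")
        recs = segment_brightfield(
            img, min_area_um2=config.min_area_um2, field_id=arm
        )
        kept, excluded = apply_exclusions(
            recs, img, focus_threshold=config.focus_threshold
        )
        counts["segmented"] += len(recs)
        counts["excluded"] += len(excluded)
        fg = labels > 0
        thr = max(
            estimate_channel_threshold(img.red, fg),
            estimate_channel_threshold(img.green, fg),
        )
        for rec in kept:
            rec.extra["conversion"] = count_color_pixels(
                rec, img.red, img.green, thr,
                conversion_cutoff=config.conversion_cutoff,
            )
            rec.extra["class_call"] = classify_structure(rec)
        records_by_time[t] = kept
    tracks = build_tracks(
        records_by_time, arm=arm,
        induction_time_h=config.induction_time_h, gate_um=config.gate_um,
    )
    return truths, records_by_time, tracks, counts


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full assay for both treatment arms and write the bundle.

    Writes under ``outdir``: per-timepoint field TIFFs and label masks
    (optional), ``structures.csv``, ``tracks.csv``, ``class_summary.csv``,
    ``conversion_summary.csv``, ``agreement_per_track.csv``,
    ``stats.json``, the resolved ``config.yaml`` and ``manifest.json``.

    Returns a dict with the in-memory results (tracks, tables, test
    results) and the output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.dump_config(config.to_dict(), outdir / "config.yaml")

    all_tracks = []
    structure_rows = []
    track_rows = []
    class_records = []
    measures = {}
    stage_counts: dict[str, int] = {}
    for arm_index, arm in enumerate(ARMS):
        try:
            truths, records_by_time, tracks, counts = _run_arm(
                config, arm, arm_index, outdir
            )
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"arm:{arm}", exc) from exc
        for key, v in counts.items():
            stage_counts[f"{arm}_{key}"] = v
        stage_counts[f"{arm}_tracks"] = len(tracks)
        for t, recs in records_by_time.items():
            for rec in recs:
                score = spherical_agreement(
                    rec.width_um, rec.height_um, rec.area_um2,
                    convention=config.convention,
                )
                conv = rec.extra["conversion"]
                call = rec.extra["class_call"]
                structure_rows.append(
                    {
                        "arm": arm,
                        "timepoint_h": t,
                        "structure_id": rec.structure_id,
                        "width_um": rec.width_um,
                        "height_um": rec.height_um,
                        "area_um2": rec.area_um2,
                        "centroid_x_um": rec.centroid_um[0],
                        "centroid_y_um": rec.centroid_um[1],
                        "label": call.label,
                        "r_um": score.r_um,
                        "spherical_like_area_um2": score.spherical_like_area_um2,
                        "percent_difference": score.percent_difference,
                        "agreement": score.agreement,
                        "convention": score.convention,
                        "red_pixels": conv.red_pixels,
                        "green_pixels": conv.green_pixels,
                        "green_fraction": conv.green_fraction,
                        "converted_call": conv.converted_call,
                    }
                )
        # classification summary over the pre-induction snapshot
        t0_recs = records_by_time[min(records_by_time)]
        class_records.extend(t0_recs)
        for tr in tracks:
            tr.track_id += 1000 * arm_index  # keep ids unique across arms
            for rec in tr.records:
                measures[(tr.track_id, rec.timepoint_h)] = rec.extra["conversion"]
                track_rows.append(
                    {
                        "arm": arm,
                        "track_id": tr.track_id,
                        "timepoint_h": rec.timepoint_h,
                        "structure_id": rec.structure_id,
                        "centroid_x_um": rec.centroid_um[0],
                        "centroid_y_um": rec.centroid_um[1],
                        "complete": tr.complete,
                    }
                )
        all_tracks.extend(tracks)

    try:
        arm_tests, per_track = paired_agreement_analysis(
            all_tracks, convention=config.convention,
            eval_time_h=config.eval_time_h,
        )
        dox = per_track[per_track["arm"] == "doxycycline"]["delta_agreement"]
        ctrl = per_track[per_track["arm"] == "control"]["delta_agreement"]
        between = two_sample_t_test(dox.to_numpy(), ctrl.to_numpy())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", exc) from exc

    conv_table = conversion_summary(all_tracks, measures)

    structures = pd.DataFrame(structure_rows)
    tracks_df = pd.DataFrame(track_rows)
    class_summary = classify_population(class_records)
    structures.to_csv(outdir / "structures.csv", index=False)
    tracks_df.to_csv(outdir / "tracks.csv", index=False)
    class_summary.to_csv(outdir / "class_summary.csv", index=False)
    conv_table.to_csv(outdir / "conversion_summary.csv", index=False)
    per_track.to_csv(outdir / "agreement_per_track.csv", index=False)

    stats_payload = {
        arm: dataclasses.asdict(res) for arm, res in arm_tests.items()
    }
    stats_payload["between_arms_delta"] = dataclasses.asdict(between)
    (outdir / "stats.json").write_text(
        json.dumps(stats_payload, indent=2, sort_keys=True) + "\n"
    )
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "counts": stage_counts,
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {
        "tracks": all_tracks,
        "structures": structures,
        "class_summary": class_summary,
        "conversion_summary": conv_table,
        "per_track": per_track,
        "arm_tests": arm_tests,
        "between_arms": between,
        "outdir": outdir,
    }
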