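"""Reporter pixel counting and conversion calls."""

import numpy as np
import pytest

from cystomorph import (
    TimeCourseConfig,
    conversion_summary,
    count_color_pixels,
    estimate_channel_threshold,
    render_field,
    segment_brightfield,
    tracked_scenario,
)
from cystomorph.simulate import ShapeParams
from cystomorph.tracking import Track


def _segment_one(single_structure_field, sp, **kw):
    img, labels, truth = single_structure_field(sp, pixel_size_um=1.0,
                                                field_size_um=420.0, **kw)
    recs = segment_brightfield(img)
    assert len(recs) == 1
    return img, recs[0], truth


class TestCountColorPixels:
    def test_all_green_structure(self, single_structure_field):
        sp = ShapeParams(kind="spheroid", width_um=100, length_um=105,
                         lumen_fraction=0.5, centroid_um=(210, 210))
        img, rec, _ = _segment_one(single_structure_field, sp,
                                   converted=True, mosaic=1.0,
                                   rng=np.random.default_rng(0))
        m = count_color_pixels(rec, img.red, img.green, threshold=5000)
        assert m.green_fraction == 1.0
        assert m.converted_call
        assert m.red_pixels == 0

    def test_half_mosaic_recovered(self, single_structure_field):
        sp = ShapeParams(kind="spheroid", width_um=120, length_um=126,
                         lumen_fraction=0.5, centroid_um=(210, 210))
        img, rec, _ = _segment_one(single_structure_field, sp,
                                   converted=True, mosaic=0.5,
                                   rng=np.random.default_rng(1))
        m = count_color_pixels(rec, img.red, img.green, threshold=5000)
        n = m.red_pixels + m.green_pixels
        # binomial tolerance: 4 sigma around 0.5 plus raster slack
        assert abs(m.green_fraction - 0.5) < 4 * 0.5 / np.sqrt(n) + 0.01

    def test_unconverted_structure_is_red(self, single_structure_field):
        sp = ShapeParams(kind="prestructure", width_um=100, length_um=100,
                         lumen_fraction=0.0, centroid_um=(210, 210))
        img, rec, _ = _segment_one(single_structure_field, sp)
        m = count_color_pixels(rec, img.red, img.green, threshold=5000)
        assert m.green_fraction == 0.0
        assert not m.converted_call

    def test_intensity_rescaling_invariance(self, single_structure_field):
        sp = ShapeParams(kind="spheroid", width_um=100, length_um=105,
                         lumen_fraction=0.5, centroid_um=(210, 210))
        img, rec, _ = _segment_one(single_structure_field, sp,
                                   converted=True, mosaic=0.7,
                                   rng=np.random.default_rng(2))
        m1 = count_color_pixels(rec, img.red, img.green, threshold=5000)
        m2 = count_color_pixels(rec, img.red.astype(float) * 2.5,
                                img.green.astype(float) * 2.5,
                                threshold=5000 * 2.5)
        assert (m1.red_pixels, m1.green_pixels) == (m2.red_pixels,
                                                    m2.green_pixels)

    def test_winner_mode_splits_double_positives(self, single_structure_field):
        sp = ShapeParams(kind="spheroid", width_um=100, length_um=105,
                         lumen_fraction=0.5, centroid_um=(210, 210))
        img, rec, _ = _segment_one(single_structure_field, sp,
                                   converted=True, mosaic=0.5,
                                   rng=np.random.default_rng(3))
        both = count_color_pixels(rec, img.red, img.green, 5000, mode="both")
        winner = count_color_pixels(rec, img.red, img.green, 5000,
                                    mode="winner")
        assert winner.red_pixels + winner.green_pixels <= (
            both.red_pixels + both.green_pixels
        )

    def test_mask_outside_image_rejected(self, single_structure_field):
        sp = ShapeParams(kind="prestructure", width_um=100, length_um=100,
                         lumen_fraction=0.0, centroid_um=(210, 210))
        img, rec, _ = _segment_one(single_structure_field, sp)
        with pytest.raises(ValueError):
            count_color_pixels(rec, img.red[:100, :100],
                               img.green[:100, :100], 5000)

    def test_records_without_mask_rejected(self):
        from cystomorph.segment import StructureRecord

        rec = StructureRecord(structure_id=1, timepoint_h=0.0,
                              pixel_size_um=1.0, width_um=10, height_um=10,
                              area_um2=100, centroid_um=(0, 0))
        with pytest.raises(ValueError):
            count_color_pixels(rec, np.zeros((4, 4)), np.zeros((4, 4)), 1.0)


def test_background_threshold_estimate():
    rng = np.random.default_rng(0)
    channel = rng.normal(500, 100, (128, 128))
    fg = np.zeros((128, 128), dtype=bool)
    fg[:64] = True
    thr = estimate_channel_threshold(channel, fg)
    bg = channel[~fg]
    assert thr == pytest.approx(bg.mean() + 2 * bg.std())


def _arm_summary(arm, seed, conversion_prob=0.8, n=16):
    """Render one post-induction field, segment, and summarize conversion."""
    tc = TimeCourseConfig(arm=arm, conversion_prob=conversion_prob,
                          mosaic_green_fraction=0.9)
    rng = np.random.default_rng(seed)
    truths = tracked_scenario(tc, rng, n_structures=n)
    img, labels = render_field(truths, 168.0, 1536.0, 1.6, noise_sd=300.0,
                               rng=rng)
    recs = segment_brightfield(img)
    thr = max(estimate_channel_threshold(img.red, labels > 0),
              estimate_channel_threshold(img.green, labels > 0))
    tracks, measures = [], {}
    for i, rec in enumerate(recs, start=1):
        tr = Track(track_id=i, arm=arm, induction_time_h=0.0)
        rec.timepoint_h = 168.0
        tr.records = [rec, rec]  # placeholder pre record not needed here
        tr.records[0] = type(rec)(
            structure_id=rec.structure_id, timepoint_h=0.0,
            pixel_size_um=rec.pixel_size_um, width_um=rec.width_um,
            height_um=rec.height_um, area_um2=rec.area_um2,
            centroid_um=rec.centroid_um,
        )
        measures[(i, 168.0)] = count_color_pixels(rec, img.red, img.green, thr)
        tracks.append(tr)
    return conversion_summary(tracks, measures)


class TestConversionSummary:
    def test_control_arm_fraction_zero(self):
        table = _arm_summary("control", seed=0)
        row = table[table["arm"] == "control"].iloc[0]
        assert row["converted_fraction"] == 0.0

    def test_doxycycline_fraction_within_binomial_interval(self):
        p, n = 0.8, 48
        converted = total = 0
        for seed in range(3):
            table = _arm_summary("doxycycline", seed=seed)
            row = table.iloc[0]
            converted += row["n_converted"]
            total += row["n_structures"]
        se = np.sqrt(p * (1 - p) / total)
        assert abs(converted / total - p) < 3 * se + 0.02

    def test_empty_arm_flagged(self):
        table = conversion_summary(
            [Track(track_id=1, arm="control", induction_time_h=0.0)],
            measures={}, differentiated_ids=set(),
        )
        assert table.iloc[0]["flag"] == "no_differentiated_structures"
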