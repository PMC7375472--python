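"""Generator contracts: class invariants, time-course dynamics, rendering
and determinism."""

import math

import numpy as np
import pytest

from cystomorph import (
    TimeCourseConfig,
    generate_structure,
    population_scenario,
    render_field,
    simulate_timecourse,
    tracked_scenario,
    truth_table,
)
from cystomorph.simulate import CLASSES, ShapeParams, SimulatedTruth


@pytest.mark.parametrize("kind", CLASSES)
def test_generated_structures_satisfy_class_invariants(kind):
    rng = np.random.default_rng(7)
    for _ in range(50):
        sp, truth = generate_structure(kind, rng)
        assert sp.length_um >= sp.width_um > 0
        assert 0.0 <= sp.lumen_fraction < 0.9
        if kind == "prestructure":
            assert sp.lumen_fraction == 0.0
        if kind == "spheroid":
            assert sp.elongation <= 1.2 + 1e-9
        if kind == "tubule":
            assert sp.elongation >= 2.0 - 1e-9
            assert 30.0 <= sp.width_um <= 80.0
        assert truth.kind == kind and not truth.converted


def test_unknown_class_rejected():
    with pytest.raises(ValueError):
        generate_structure("cyst", np.random.default_rng(0))
    with pytest.raises(ValueError):
        ShapeParams(kind="blob", width_um=10, length_um=20, lumen_fraction=0)


def test_degenerate_capsule_is_disk():
    sp = ShapeParams(kind="spheroid", width_um=100, length_um=100,
                     lumen_fraction=0.6)
    assert sp.elongation == 1.0
    bw, bh = sp.bbox_um()
    assert bw == bh == 100.0


def _tubule_truth(e0=5.0, width=50.0):
    sp = ShapeParams(kind="tubule", width_um=width, length_um=width * e0,
                     lumen_fraction=0.3, centroid_um=(300, 300))
    return SimulatedTruth(structure_id=1, kind="tubule", baseline=sp)


def test_relaxation_closed_form():
    """E(t) = 1 + (E0-1) exp(-lambda t): with exp(-168 lambda) = 0.2 and
    E0 = 5 the elongation at 168 h is exactly 1.8."""
    lam = -math.log(0.2) / 168.0
    tc = TimeCourseConfig(arm="doxycycline", relaxation_rate_per_h=lam,
                          conversion_prob=1.0, jitter_sd=0.0, drift_sd_um=0.0)
    truth = _tubule_truth(e0=5.0)
    simulate_timecourse([truth], tc, np.random.default_rng(0))
    assert truth.converted
    assert truth.shapes[168.0].elongation == pytest.approx(1.8, abs=1e-12)
    assert truth.shapes[168.0].width_um == pytest.approx(50.0)


def test_zero_rate_zero_jitter_is_identity():
    tc = TimeCourseConfig(arm="doxycycline", relaxation_rate_per_h=0.0,
                          conversion_prob=1.0, jitter_sd=0.0, drift_sd_um=0.0)
    truth = _tubule_truth()
    simulate_timecourse([truth], tc, np.random.default_rng(0))
    for sp in truth.shapes.values():
        assert sp.width_um == truth.baseline.width_um
        assert sp.length_um == truth.baseline.length_um
        assert sp.centroid_um == truth.baseline.centroid_um


def test_control_arm_never_converts():
    tc = TimeCourseConfig(arm="control", conversion_prob=0.99)
    assert tc.conversion_prob == 0.0  # control forces it to zero
    rng = np.random.default_rng(3)
    truths = tracked_scenario(tc, rng, n_structures=15)
    assert not any(t.converted for t in truths)


def test_prestructure_immune_to_conversion_and_relaxation():
    sp = ShapeParams(kind="prestructure", width_um=60, length_um=80,
                     lumen_fraction=0.0, centroid_um=(200, 200))
    truth = SimulatedTruth(structure_id=1, kind="prestructure", baseline=sp)
    tc = TimeCourseConfig(arm="doxycycline", conversion_prob=1.0,
                          jitter_sd=0.0, drift_sd_um=0.0)
    simulate_timecourse([truth], tc, np.random.default_rng(0))
    assert not truth.converted
    for s in truth.shapes.values():
        assert s.length_um == 80.0


def test_timecourse_validation():
    with pytest.raises(ValueError):
        simulate_timecourse([], TimeCourseConfig(), np.random.default_rng(0))
    with pytest.raises(ValueError):
        TimeCourseConfig(timepoints_h=(0.0, 48.0, 48.0))
    with pytest.raises(ValueError):
        TimeCourseConfig(arm="placebo")
    with pytest.raises(ValueError):
        # no post-induction timepoint >= 96 h
        simulate_timecourse([_tubule_truth()],
                            TimeCourseConfig(timepoints_h=(0.0, 48.0)),
                            np.random.default_rng(0))


def test_identical_seeds_reproduce_truth_and_images_bitwise():
    def make(seed):
        tc = TimeCourseConfig(arm="doxycycline")
        rng = np.random.default_rng(seed)
        truths = tracked_scenario(tc, rng, n_structures=8,
                                  field_size_um=1024.0)
        img, labels = render_field(truths, 168.0, 1024.0, 1.6,
                                   noise_sd=300.0, rng=rng)
        return truth_table(truths, 1024.0), img, labels

    t1, img1, lab1 = make(11)
    t2, img2, lab2 = make(11)
    assert t1.equals(t2)
    assert np.array_equal(img1.brightfield, img2.brightfield)
    assert np.array_equal(img1.red, img2.red)
    assert np.array_equal(img1.green, img2.green)
    assert np.array_equal(lab1, lab2)


def test_conversion_rate_matches_binomial_expectation():
    """Seed-averaged converted fraction approaches conversion_prob."""
    p, n_seeds, n = 0.8, 30, 20
    fracs = []
    for seed in range(n_seeds):
        tc = TimeCourseConfig(arm="doxycycline", conversion_prob=p)
        truths = tracked_scenario(tc, np.random.default_rng(seed),
                                  n_structures=n)
        fracs.append(np.mean([t.converted for t in truths]))
    se = math.sqrt(p * (1 - p) / (n_seeds * n))
    assert abs(np.mean(fracs) - p) < 4 * se


def test_render_flags_and_channels(single_structure_field):
    # fully green mosaic leaves no red inside the structure
    sp = ShapeParams(kind="spheroid", width_um=80, length_um=88,
                     lumen_fraction=0.5, centroid_um=(200, 200))
    img, labels, truth = single_structure_field(
        sp, converted=True, mosaic=1.0, rng=np.random.default_rng(0)
    )
    inside = labels == 1
    assert inside.any()
    assert (img.green[inside] > 10000).all()
    assert (img.red[inside] < 1000).all()

    # structure centered outside the field is flagged border-clipped
    sp2 = ShapeParams(kind="spheroid", width_um=80, length_um=88,
                      lumen_fraction=0.5, centroid_um=(395, 200))
    truth2 = SimulatedTruth(structure_id=1, kind="spheroid", baseline=sp2,
                            shapes={0.0: sp2})
    assert truth2.border_clipped(0.0, 400.0)

    with pytest.raises(ValueError):
        render_field([truth], 0.0, 400.0, -1.0)


def test_population_scenario_mixture_and_layout():
    rng = np.random.default_rng(5)
    truths = population_scenario(30, rng,
                                 class_probs={"spheroid": 0.5, "tubule": 0.5})
    kinds = {t.kind for t in truths}
    assert kinds <= {"spheroid", "tubule"}
    # all structures fully inside the field
    assert not any(t.border_clipped(0.0, 1536.0) for t in truths)
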