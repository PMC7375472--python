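import numpy as np
import pytest

from cystomorph import SimulatedTruth, render_field
from cystomorph.simulate import ShapeParams


@pytest.fixture
def single_structure_field():
    """Render one hand-specified structure, noise-free, on its own field.

    Returns a function (shape_params, pixel_size_um, field_size_um) ->
    (FieldImage, labels, SimulatedTruth).
    """

    def _render(sp: ShapeParams, pixel_size_um=1.0, field_size_um=400.0,
                timepoint_h=0.0, converted=False, mosaic=0.0, rng=None):
        truth = SimulatedTruth(
            structure_id=1, kind=sp.kind, baseline=sp,
            converted=converted, mosaic_green_fraction=mosaic,
            shapes={timepoint_h: sp},
        )
        img, labels = render_field(
            [truth], timepoint_h, field_size_um, pixel_size_um, rng=rng
        )
        return img, labels, truth

    return _render


@pytest.fixture
def match_by_label():
    """Map a segmented record back to the ground-truth id via the label mask."""

    def _match(record, labels) -> int:
        r0, c0, r1, c1 = record.bbox_px
        ids = labels[r0:r1, c0:c1][record.mask]
        ids = ids[ids > 0]
        if ids.size == 0:
            return -1
        vals, counts = np.unique(ids, return_counts=True)
        return int(vals[np.argmax(counts)])

    return _match
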