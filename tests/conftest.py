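import numpy as np
import pytest

from pollieval.annotations import Box, GroundTruthAnnotation, Prediction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gt(
    x, y, w, h, image_id="S0_000001.jpg", session_id="S0", frame_index=1,
    taxon="Hymenoptera", individual_id="A", is_roi=False, co_occurring=False,
):
    return GroundTruthAnnotation(
        image_id=image_id,
        session_id=session_id,
        frame_index=frame_index,
        box=Box(x, y, w, h),
        taxon=taxon,
        individual_id=individual_id,
        is_roi=is_roi,
        co_occurring=co_occurring,
    )


def make_pred(x, y, w, h, image_id="S0_000001.jpg", label="Hymenoptera", confidence=0.9):
    return Prediction(image_id=image_id, box=Box(x, y, w, h), label=label, confidence=confidence)


def random_boxes(rng, n, span=100.0, min_size=1.0, max_size=40.0):
    """n random boxes inside [0, span)^2."""
    out = []
    for _ in range(n):
        w = rng.uniform(min_size, max_size)
        h = rng.uniform(min_size, max_size)
        x = rng.uniform(0, span - w)
        y = rng.uniform(0, span - h)
        out.append(Box(x, y, w, h))
    return out
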