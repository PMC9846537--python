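import numpy as np
import pytest

from penquant import (
    BBox,
    Detection,
    DetectionClass,
    FrameRecord,
    Lighting,
    default_geometry,
    to_detection_class,
)


@pytest.fixture
def geometry():
    return default_geometry()


def detections_from_truth(frames, confidence=1.0):
    """Perfect detections: one per ground-truth instance."""
    return {
        fr.frame_index: [
            Detection(
                box=inst.box,
                detection_class=to_detection_class(inst.category),
                confidence=confidence,
            )
            for inst in fr.instances
        ]
        for fr in frames
    }


def make_frame(instances, frame_index=0, timestamp=None, pen_id="pen-1", lighting=Lighting.RGB):
    return FrameRecord(
        frame_index=frame_index,
        timestamp=float(frame_index) if timestamp is None else timestamp,
        lighting=lighting,
        pen_id=pen_id,
        instances=tuple(instances),
    )


def random_box(rng, lo=0.0, hi=500.0, min_side=5.0, max_side=120.0):
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    x0 = rng.uniform(lo, hi - w)
    y0 = rng.uniform(lo, hi - h)
    return BBox(x0, y0, x0 + w, y0 + h)
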