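import numpy as np
import pytest

from cytolapse.annotations import (
    CLASS_ORDER,
    Box,
    CellClass,
    FrameAnnotation,
    LabelledObject,
    SampleMeta,
    VideoAnnotation,
)


def make_box(rng: np.random.Generator, field=(1388, 1040)) -> Box:
    w = float(rng.uniform(10, 50))
    h = float(rng.uniform(10, 50))
    x0 = float(rng.uniform(0, field[0] - w))
    y0 = float(rng.uniform(0, field[1] - h))
    return Box(round(x0, 2), round(y0, 2), round(x0 + w, 2), round(y0 + h, 2))


def make_video(
    seed: int = 0,
    n_frames: int = 3,
    n_objects: int = 8,
    with_ids: bool = True,
    interval: float = 5.0,
) -> VideoAnnotation:
    """A small random but valid video, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    frames = []
    for fi in range(1, n_frames + 1):
        objects = []
        for k in range(n_objects):
            objects.append(
                LabelledObject(
                    box=make_box(rng),
                    cls=CLASS_ORDER[int(rng.integers(0, 4))],
                    confidence=float(np.round(rng.uniform(0.05, 1.0), 6)),
                    object_id=str(k) if with_ids else None,
                )
            )
        frames.append(
            FrameAnnotation(frame_index=fi, time_min=fi * interval, objects=objects)
        )
    return VideoAnnotation(
        frames=frames,
        frame_interval_min=interval,
        sample_meta=SampleMeta(sample_id="fixture", dose_gy=4.0, irradiated=True),
    )


@pytest.fixture
def random_video() -> VideoAnnotation:
    return make_video(seed=42)
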