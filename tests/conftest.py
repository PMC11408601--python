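import numpy as np
import pytest

from mimsquant import (
    ChromatinTexture,
    Disc,
    Ellipse,
    MassImageStack,
    SceneSpec,
    build_scene,
    sample_counts,
)


def make_stack(channels: dict, pixel_size_nm: float = 100.0) -> MassImageStack:
    """Stack from plain arrays (helper for hand-built fixtures)."""
    return MassImageStack(
        channels={k: np.asarray(v, dtype=np.int64) for k, v in channels.items()},
        pixel_size_nm=pixel_size_nm,
    )


def flat_scene_spec(**overrides) -> SceneSpec:
    """A small nucleus scene with flat chromatin texture (exact compartment
    enrichments) used throughout the recovery tests."""
    defaults = dict(
        image_shape=(64, 64),
        pixel_size_nm=100.0,
        nucleus=Ellipse((32, 32), (22, 17)),
        nucleoli=(Disc((28, 27), 6.0),),
        lamina_width_px=3.0,
        chromatin_texture=ChromatinTexture(amplitude=0.0, focus_count=0),
        seed=7,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def flat_truth():
    return build_scene(flat_scene_spec())


@pytest.fixture(scope="session")
def flat_stack(flat_truth):
    return sample_counts(flat_truth, seed=11)
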