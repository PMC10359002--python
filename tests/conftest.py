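import numpy as np
import pytest

from mosquitrack import (
    ClutterRegion,
    SceneSpec,
    Track,
    apply_observation_model,
    generate_scene,
)


@pytest.fixture
def clean_scene():
    """Zero-noise, clutter-free scene: 2 flying + 3 resting, 540 frames."""
    return generate_scene(
        SceneSpec(seed=11, n_flying=2, n_resting=3, noise_sigma_px=0.0)
    )


@pytest.fixture
def noisy_cluttered_scene():
    """σ=1 px noise with one dropout rectangle in mid-arena."""
    region = ClutterRegion(220, 160, 340, 280, dropout_prob=0.8)
    return generate_scene(
        SceneSpec(
            seed=0,
            n_flying=2,
            n_resting=3,
            noise_sigma_px=1.0,
            clutter_regions=(region,),
        )
    )


@pytest.fixture
def exact_detections(clean_scene):
    dets, miss = apply_observation_model(clean_scene)
    assert not miss.any()
    return dets


def straight_track(track_id=1, n=10, x0=10.0, y0=20.0, vx=2.0, vy=1.0, frames=None):
    """Constant-velocity track helper used across test modules."""
    if frames is None:
        frames = np.arange(1, n + 1)
    frames = np.asarray(frames)
    return Track(
        track_id=track_id,
        frames=frames,
        x=x0 + vx * (frames - frames[0]),
        y=y0 + vy * (frames - frames[0]),
    )
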