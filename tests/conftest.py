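"""Shared fixtures: small synthetic scenes rendered once per session."""

import numpy as np
import pytest

from endovo.synthetic_scene import SceneConfig, render_sequence


@pytest.fixture(scope="session")
def rigid_seq():
    """Bumped rigid scene with camera motion (default study conditions)."""
    return render_sequence(SceneConfig(scenario="rigid", n_frames=5, seed=3))


@pytest.fixture(scope="session")
def rigid_obs(rigid_seq):
    return rigid_seq.frame_observations()


@pytest.fixture(scope="session")
def planar_seq():
    """Planar pure-translation rigid scene: bilinear warping exact."""
    return render_sequence(
        SceneConfig(
            scenario="rigid",
            n_frames=5,
            seed=7,
            n_bumps=0,
            specularity_count=0,
            camera_translation_only=True,
        )
    )


@pytest.fixture(scope="session")
def planar_obs(planar_seq):
    return planar_seq.frame_observations()


@pytest.fixture(scope="session")
def deforming_seq():
    """Small deforming scene (static camera, tool poke)."""
    return render_sequence(
        SceneConfig(scenario="deforming", width=40, height=32, n_frames=8, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
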