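"""Shared fixtures: pinned-seed synthetic scenes at various noise levels."""

import pytest

from synaptomo import registration, segmentation
from synaptomo.synthetic_data import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """Default study-conditions scene (jitter, noise, speckles), seed-pinned."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, jitter-free, speckle-free scene for exactness checks."""
    cfg = SceneConfig(seed=7, background_noise_sd=0.0, speckle_count=0, jitter_px=0)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def aligned_default(default_scene):
    _, series = default_scene
    stacks, transform = registration.align_series(series)
    return stacks, transform


@pytest.fixture(scope="session")
def masks_default(aligned_default):
    stacks, _ = aligned_default
    return {role: segmentation.binarize_stack(s) for role, s in stacks.items()}
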