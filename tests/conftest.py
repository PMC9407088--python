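"""Shared fixtures: phantoms and precomputed feature sets.

Everything is generated programmatically at test time from fixed seeds;
expensive feature detection is session-scoped so each slice is processed
once.
"""

import numpy as np
import pytest

from fmritemplate import (
    FeatureParams,
    describe_all,
    make_textured_phantom,
)
from fmritemplate.scale_space_features import detect_features_with_pyramid


@pytest.fixture(scope="session")
def phantom64():
    """64×64×3 clean phantom volume, seed 0."""
    return make_textured_phantom(64, 64, 3, seed=0)


@pytest.fixture(scope="session")
def phantom96_slice():
    """One 96×96 phantom slice at the tool's native resolution."""
    return make_textured_phantom(96, 96, 1, seed=0)[:, :, 0]


@pytest.fixture(scope="session")
def upsample_params():
    """Detector configuration with the small-image 2x octave enabled."""
    return FeatureParams(upsample=True)


@pytest.fixture(scope="session")
def features96(phantom96_slice, upsample_params):
    """(keypoints, pyramid, descriptors) of the native-size slice."""
    kps, gp = detect_features_with_pyramid(phantom96_slice, upsample_params)
    descs = describe_all(gp, kps)
    return kps, gp, descs


@pytest.fixture(scope="session")
def features64(phantom64):
    """(keypoints, pyramid, descriptors) of a 64×64 slice, default params."""
    kps, gp = detect_features_with_pyramid(phantom64[:, :, 0])
    descs = describe_all(gp, kps)
    return kps, gp, descs
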