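"""Shared fixtures: one rendered default subject reused across tests.

Rendering and preprocessing are the expensive steps, so the default
body's averaging window, segmented silhouette and detected landmarks
are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from backmark import BackModelParams, detect_landmarks, render_frames
from backmark.config import PreprocessingConfig
from backmark.preprocessing import preprocess_frames
from backmark.synthetic import BackSurface


@pytest.fixture(scope="session")
def default_params() -> BackModelParams:
    return BackModelParams()


@pytest.fixture(scope="session")
def default_surface(default_params) -> BackSurface:
    return BackSurface(default_params)


@pytest.fixture(scope="session")
def rendered_window(default_surface):
    """Ten noise realizations of the default body plus ground truth."""
    frames, gt = render_frames(default_surface, n=10, seed=7)
    return frames, gt


@pytest.fixture(scope="session")
def subject_cloud(rendered_window):
    frames, _ = rendered_window
    cloud, _roi = preprocess_frames(frames, config=PreprocessingConfig())
    return cloud


@pytest.fixture(scope="session")
def detected_landmarks(subject_cloud):
    return detect_landmarks(subject_cloud)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
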