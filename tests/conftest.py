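"""Shared fixtures: desk-scale study settings and cached synthetic subjects.

Cohort-level tests run at the package's desk scale: 8-second clips at
12.5 fps (100 frames), 36x36 px frames, a 36-px encoder input so no resize
is needed, and a compact recurrent classifier.  These sizes keep the full
suite within a single-CPU budget while preserving every class contrast the
generator documents.
"""

from __future__ import annotations

import numpy as np
import pytest

from ststp.model import Hyperparams
from ststp.pipeline import ModelParams, RunConfig, extract_blocks
from ststp.synthgen import ScenarioConfig, generate_subject

#: desk-scale generation base shared by cohort tests
DESK_BASE = ScenarioConfig(n_frames=100, fps=12.5, frame_size=(36, 36))

#: desk-scale classifier settings shared by cohort tests
DESK_HYPER = Hyperparams(hidden=16, batch_size=64, max_epochs=12, lr=0.1)


def desk_runconfig(seed: int = 0) -> RunConfig:
    return RunConfig(model=ModelParams(encoder_input=36), seed=seed)


def extract_cohort(subjects, config: RunConfig, encoder=None):
    """Modality blocks + labels for a list of synthetic subjects."""
    blocks = []
    for s in subjects:
        b = extract_blocks(s.clip, s.landmarks, config, encoder)
        blocks.append({k: b[k] for k in ("CNN", "OF", "HAND_RAW", "EAR")})
    return blocks, [s.label for s in subjects]


@pytest.fixture(scope="session")
def small_subject():
    """One deterministic synthetic subject used across unit tests."""
    return generate_subject(ScenarioConfig(
        seed=7, n_frames=60, fps=12.5, frame_size=(48, 48), blink_rate=30.0))


@pytest.fixture(scope="session")
def textured_frame():
    """A smooth textured grayscale frame with trackable corners."""
    from scipy import ndimage

    rng = np.random.default_rng(11)
    img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 1.5)
    return (img - img.min()) / np.ptp(img) * 255.0
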