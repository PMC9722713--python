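"""Shared fixtures: synthetic renders and digitised records, built once."""

from __future__ import annotations

import numpy as np
import pytest

from paperecg import TemplateRecogniser, digitise_image
from paperecg.synth import generate_synthetic_ecg


@pytest.fixture(scope="session")
def recogniser():
    return TemplateRecogniser()


@pytest.fixture(scope="session")
def truth_3x4():
    """Zero-noise, zero-overlap 3x4+rhythm render at 250 dpi."""
    return generate_synthetic_ecg(seed=1, layout_kind="3x4_rhythm", noise_density=0.0)


@pytest.fixture(scope="session")
def digitised_3x4(truth_3x4, recogniser):
    record, debug = digitise_image(
        truth_3x4.image, recogniser=recogniser, return_debug=True
    )
    return record, debug


@pytest.fixture(scope="session")
def truth_3x1():
    return generate_synthetic_ecg(seed=2, layout_kind="3x1", noise_density=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
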