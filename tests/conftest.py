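"""Shared fixtures: one small featurized stimulus set reused across unit tests."""

from dataclasses import replace

import numpy as np
import pytest

from frfnet import frontend, io, stimuli


@pytest.fixture(scope="session")
def tiny_design():
    """64-px scaled orientation-identification design (fast to generate)."""
    return stimuli.scaled_design("exp1_var", 64, 8)


@pytest.fixture(scope="session")
def tiny_features(tiny_design):
    """Featurized 60-trial set from the tiny design: (X, metadata, config)."""
    config = frontend.FrontendConfig.for_design(tiny_design, grid=8)
    X, meta = io.featurize_design(tiny_design, 60, 7, config)
    return X, meta, config


@pytest.fixture(scope="session")
def fixed_level_design():
    """Fixed suprathreshold level variant of the tiny design."""
    d = stimuli.scaled_design("exp1_fix", 64, 8)
    return replace(d, levels=(0.32,))
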