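"""Shared fixtures: presets and scaled-down end-to-end pipeline runs.

The pipeline fixtures run a frozen-signal ensemble at each variant's reference
noise conditions and extract/classify spike-evoking epochs once per session;
several tests (action statistics, gating-variable statistics, tertile
analysis, partition invariants) share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from strml.model import TYPE_I, TYPE_II
from strml.experiments import ExperimentConfig, run_see_pipeline, build_epoch_library


@pytest.fixture(scope="session")
def type1_params():
    return TYPE_I


@pytest.fixture(scope="session")
def type2_params():
    return TYPE_II


@pytest.fixture(scope="session")
def pipeline_type2():
    """Type II reference run: delta1=5, delta2=1.64, tau=3 ms, 30 trials, 120 s."""
    cfg = ExperimentConfig(variant="TypeII", n_trials=30, duration=120500.0, seeds=[11])
    return run_see_pipeline(cfg, seed=11)


@pytest.fixture(scope="session")
def pipeline_type1():
    """Type I reference run: delta1=2, delta2=0.91, tau=7 ms, 30 trials, 60 s."""
    cfg = ExperimentConfig(variant="TypeI", n_trials=30, duration=60500.0, seeds=[11])
    return run_see_pipeline(cfg, seed=11)


@pytest.fixture(scope="session")
def epoch_library_type2():
    """Small labelled epoch library harvested from fresh Type II segments."""
    return build_epoch_library(TYPE_II, n_segments=2, segment_duration=8000.0,
                               seed=3, n_trials=8, max_sees=40, max_nonspiking=25)
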