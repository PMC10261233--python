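"""Shared fixtures: phantom cohorts and trained toy models.

Training and held-out evaluation are session-scoped — the heart
segmenter, slice classifier and decomposition CycleGAN are each trained
once per test run and shared between the module tests and the
end-to-end checks. All training is seeded and deterministic.
"""

import numpy as np
import pytest

from cacforge import decomposition as dec
from cacforge import phantom, pipeline, roi

TRAIN_SEED = 42
HELDOUT_SEED = 43


@pytest.fixture(scope="session")
def train_prepared():
    cases = phantom.generate_cohort(16, seed=TRAIN_SEED, lesion_rate=(1, 4))
    return [pipeline.prepare_case(c) for c in cases]


@pytest.fixture(scope="session")
def heldout_prepared():
    cases = phantom.generate_cohort(14, seed=HELDOUT_SEED, lesion_rate=(0, 4))
    return [pipeline.prepare_case(c) for c in cases]


@pytest.fixture(scope="session")
def heart_model(train_prepared):
    data = [(p.ctac_rest, p.heart_ctac) for p in train_prepared[:8]]
    return roi.train_heart_segmenter(data, roi.SegConfig(steps=250, lr=1e-3, seed=0))


@pytest.fixture(scope="session")
def slice_model(train_prepared):
    x, y = pipeline.build_classifier_training(train_prepared)
    return roi.train_slice_classifier(x, y, roi.ClsConfig(seed=0))


@pytest.fixture(scope="session")
def decomp_model(train_prepared):
    cac, nocac = pipeline.build_decomposition_domains(train_prepared)
    config = dec.CycleGANConfig(iterations=3000, lr=3e-4, channels=8, seed=0)
    return dec.train_cyclegan(cac, nocac, config)


@pytest.fixture(scope="session")
def decomp_recovery(decomp_model, heldout_prepared):
    """Held-out per-slice mass recovery, computed once."""
    return pipeline.decomposition_recovery(decomp_model, heldout_prepared)


@pytest.fixture(scope="session")
def roi_scores(heart_model, slice_model, heldout_prepared):
    """Held-out Dice / slice accuracy, computed once."""
    return pipeline.roi_recovery(heart_model, slice_model, heldout_prepared)


@pytest.fixture(scope="session")
def demo_report():
    """One shared demo run (the demo itself is deterministic)."""
    return pipeline.demo(pipeline.DemoConfig())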