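"""Shared fixtures: phantoms, registrations and cohort analyses are
session-scoped because they are the expensive inputs reused across files."""

from __future__ import annotations

import numpy as np
import pytest

from lungdeform import DeformationModel, make_phantom, register_elastic
from lungdeform.pipeline import PipelineConfig, analyze_cohort
from lungdeform.preprocess import dilate_mask
from lungdeform.synthetic import make_cohort

# 48^3 at 8/3 mm covers the same 128 mm field of view as the default
# 64^3 / 2 mm grid; used where many subjects are processed.
COARSE = dict(grid_shape=(48, 48, 48), spacing=8.0 / 3.0)


@pytest.fixture(scope="session")
def default_model() -> DeformationModel:
    return DeformationModel(seed=3)


@pytest.fixture(scope="session")
def phantom(default_model):
    """One textured default phantom (64^3, 2 mm): the registration target."""
    return make_phantom(default_model, subject_id="sub-fix", group="control")


@pytest.fixture(scope="session")
def phantom_roi(phantom):
    return dilate_mask(phantom.lung_mask_exp, 5)  # 10 mm at 2 mm spacing


@pytest.fixture(scope="session")
def builtin_reg(phantom, phantom_roi):
    """Builtin-backend registration of the default phantom pair."""
    return register_elastic(
        phantom.expiration, phantom.inspiration, phantom_roi, backend="builtin"
    )


@pytest.fixture(scope="session")
def oracle_analysis():
    """8 + 8 cohort analysed with ground-truth (oracle) registration."""
    subjects, table = make_cohort(8, 8, seed=42, **COARSE)
    cfg = PipelineConfig(backend="oracle", spacing=COARSE["spacing"])
    tab, art = analyze_cohort(subjects, table, cfg)
    return subjects, tab, art
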