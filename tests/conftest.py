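"""Shared fixtures: phantoms, calibrated cohort, constructed label images."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from octfib import phantom
from octfib.pipeline import extract_features


def disk_mask(shape, center, radius):
    """Pixels whose centers lie within ``radius`` of ``center`` (inclusive)."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Twenty phantoms per class at the calibrated presets, with ground truth."""
    return phantom.generate_cohort(phantom.class_presets(), n_per_class=20, seed=11)


@pytest.fixture(scope="session")
def cohort_features(calibrated_cohort):
    """Per-patch feature table of the calibrated cohort (full pipeline)."""
    rows = []
    for pair, _truth, _label in calibrated_cohort:
        r, _ = extract_features(pair)
        rows.extend(r)
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
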