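"""Shared fixtures: small synthetic cohorts and light scoring helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micronet import preprocess as prep
from micronet import synthetic as synth

IMMUNE = list(synth.IMMUNE_MODULES)


def null_truth(seed: int, **kwargs) -> synth.SyntheticTruth:
    """Truth with every causal path coefficient set to zero."""
    coeffs = {k: 0.0 for k in synth.DEFAULT_COEFFS}
    return synth.default_truth(seed=seed, coeffs=coeffs, **kwargs)


def light_scores(truth: synth.SyntheticTruth):
    """Cohort -> log2 expression -> immune-module meta-features.

    The minimal scoring path (no quantile/batch steps) used where a test
    exercises a downstream stage rather than preprocessing itself.
    """
    expr, assign, phen = synth.generate_cohort(truth)
    logged = prep.log2_transform(expr)
    scores = prep.module_scores(logged, assign, IMMUNE)
    return scores, phen


@pytest.fixture(scope="session")
def small_truth() -> synth.SyntheticTruth:
    return synth.default_truth(seed=42, n_subjects=150, genes_per_module=20, n_unassigned=40)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    return synth.generate_cohort(small_truth)


@pytest.fixture(scope="session")
def small_scores(small_truth):
    return light_scores(small_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
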