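"""Shared fixtures: a reduced synthetic cohort (default class profiles,
study-proportional class imbalance, desk-scale counts) with its extracted
raw-variant feature tables, plus small deterministic toy tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qeegml import CohortSpec, default_profiles
from qeegml.pipeline import cohort_feature_tables

TEST_COHORT_SEED = 11


def small_cohort_spec(seed: int = TEST_COHORT_SEED) -> CohortSpec:
    """Default profiles at ~1/6.5 of the study's class counts (imbalance
    preserved: train 12/15/18, IV 4/7/8), 240-s recordings."""
    return CohortSpec(
        profiles=default_profiles(),
        n_train={"normal": 12, "TBI": 15, "stroke": 18},
        n_iv={"normal": 4, "TBI": 7, "stroke": 8},
        seed=seed,
        duration_s=240.0,
    )


@pytest.fixture(scope="session")
def cohort_tables():
    """(spec, {"train": (table, labels), "iv": (table, labels)}) for the
    reduced cohort, raw signal variant, broadband coherence included."""
    spec = small_cohort_spec()
    tables = cohort_feature_tables(spec, variant="raw", seed=5)
    return spec, tables


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_table(rng):
    """60 x 20 noise table, two classes, features f0-f4 shifted by 2.5 SD."""
    X = rng.standard_normal((60, 20))
    y = np.array(["A"] * 30 + ["B"] * 30)
    X[y == "B", :5] += 2.5
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(20)]), pd.Series(y)
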