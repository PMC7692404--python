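import logging

import numpy as np
import pandas as pd
import pytest

from ipscore import (ExpressionMatrix, SimulationConfig, build_reference,
                     classify, ips_matrix, null_config, null_stats,
                     planted_config, simulate_cohort)

logging.getLogger("ipscore").setLevel(logging.ERROR)


@pytest.fixture
def hand_reference():
    """Two-gene reference x=(1,2,3), y=(1,3,2): PCC_n = 0.5."""
    ref = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]],
                       index=["GX", "GY"], columns=["s1", "s2", "s3"])
    return build_reference(ref, [("GX", "GY")])


@pytest.fixture
def identity_reference():
    """Two perfectly correlated genes x = y = (1,2,3)."""
    ref = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
                       index=["GX", "GY"], columns=["s1", "s2", "s3"])
    return build_reference(ref, [("GX", "GY")])


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples (2 normal, 2 tumor) ExpressionMatrix."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 0.0, 1.0, 5.0], [0.5, 1.5, 2.5, 3.5]],
        index=["GA", "GB", "GC"], columns=["n1", "n2", "t1", "t2"])
    groups = pd.Series({"n1": "normal", "n2": "normal",
                        "t1": "tumor", "t2": "tumor"})
    return ExpressionMatrix(values, groups, cohort_label="TOY")


@pytest.fixture(scope="session")
def planted():
    """The standard planted cohort with its scores and calls, computed once."""
    cohort = simulate_cohort(planted_config(seed=1))
    ips = ips_matrix(cohort.expression, cohort.pathways)
    calls = classify(ips, null_stats(ips))
    return cohort, ips, calls


@pytest.fixture(scope="session")
def null_cohort():
    """No-perturbation cohort for calibration tests (smaller than the
    acceptance-scale one)."""
    cohort = simulate_cohort(null_config(seed=3, n_pathways=30))
    ips = ips_matrix(cohort.expression, cohort.pathways)
    calls = classify(ips, null_stats(ips))
    return cohort, ips, calls
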