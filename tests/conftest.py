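"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mcda_panel import RatingMatrix, default_criteria_set

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def criteria():
    return default_criteria_set()


def make_matrix(values, role, session="test", raters=None, crits=None, scale=None):
    """Build a RatingMatrix from a 2-D array-like (raters x criteria)."""
    arr = np.asarray(values)
    raters = raters or [f"R{i + 1}" for i in range(arr.shape[0])]
    crits = crits or [f"C{j + 1}" for j in range(arr.shape[1])]
    return RatingMatrix(
        pd.DataFrame(arr, index=raters, columns=crits),
        role=role,
        session=session,
        scale=scale,
    )


def icc_oracle(test, retest):
    """Brute-force two-way ANOVA ICC(3,1), written with explicit loops.

    Independent of the package's vectorized mean-squares path: every sum of
    squares is accumulated element by element from first principles.
    """
    test = [float(v) for v in test]
    retest = [float(v) for v in retest]
    n, k = len(test), 2
    x = [[test[i], retest[i]] for i in range(n)]
    grand = sum(v for row in x for v in row) / (n * k)
    unit_means = [sum(row) / k for row in x]
    session_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_units = k * sum((m - grand) ** 2 for m in unit_means)
    ss_sessions = n * sum((m - grand) ** 2 for m in session_means)
    ss_error = ss_total - ss_units - ss_sessions
    bms = ss_units / (n - 1)
    ems = ss_error / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + ems)
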