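import warnings

import numpy as np
import pandas as pd
import pytest

from prognosig.containers import ClinicalTable, ExpressionMatrix
from prognosig.simulate import CohortSpec, SimulationConfig, simulate_cohorts


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline stages warn on intersections/skipped folds; tests opt in."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_expr():
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]],
        index=["GENE1", "GENE2", "GENE3"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(vals, cohort="c0")


@pytest.fixture
def small_cohort():
    """One simulated 60-sample cohort with 5 planted genes."""
    cfg = SimulationConfig(
        n_genes=80,
        n_prognostic=5,
        cohorts=(CohortSpec("c", 60, 0.0),),
        beta=1.0,
        seed=123,
    )
    exprs, clins, truth = simulate_cohorts(cfg)
    return exprs["c"], clins["c"], truth


def random_survival(rng, n, censor_frac=0.25):
    times = rng.exponential(20.0, n) + 0.5
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return times, events
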