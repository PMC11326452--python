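import numpy as np
import pandas as pd
import pytest

from polrboot.data_model import (
    CategoricalPredictorSpec,
    DesignMatrix,
    OrdinalOutcomeSpec,
    StudyDataset,
)


@pytest.fixture
def outcome3():
    return OrdinalOutcomeSpec("severity", ("low", "mid", "high"))


@pytest.fixture
def binary_predictor():
    return CategoricalPredictorSpec("exposed", ("no", "yes"), reference="no")


@pytest.fixture
def toy_dataset(outcome3, binary_predictor):
    """40 records, 1 binary predictor, all outcome levels observed.

    Constructed deterministically so fits and oracles are reproducible.
    """
    rng = np.random.default_rng(42)
    exposed = rng.random(40) < 0.5
    # outcome drawn from a genuine cumulative-logit model, beta = 1.2
    eta = 1.2 * exposed.astype(float)
    from scipy.special import expit

    th = np.array([-0.5, 0.8])
    cum = expit(th[None, :] - eta[:, None])
    u = rng.random(40)
    codes = (u[:, None] > np.hstack([cum, np.ones((40, 1))])).sum(axis=1)
    levels = np.array(outcome3.ordered_levels, dtype=object)
    frame = pd.DataFrame(
        {
            "exposed": np.where(exposed, "yes", "no"),
            "severity": levels[codes],
        }
    )
    return StudyDataset(outcome3, [binary_predictor], frame)


def make_intercept_only_design(counts, levels=("low", "mid", "high")):
    """Design with zero predictors and the given per-category counts."""
    codes = np.concatenate(
        [np.full(c, j + 1, dtype=int) for j, c in enumerate(counts)]
    )
    return DesignMatrix(
        columns=[],
        values=np.empty((codes.size, 0)),
        outcome_codes=codes,
        outcome_levels=tuple(levels),
    )
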