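import numpy as np
import pytest

from templatest.session import PopulationSession, TrialRecord


def make_session(
    responses,
    conditions,
    outcomes=None,
    modality="continuous",
    covariates=None,
):
    """Build a session from raw pieces with auto-generated ids."""
    responses = np.asarray(responses, dtype=float)
    n = responses.shape[0]
    outcomes = outcomes or ["hit"] * n
    covariates = covariates or [{}] * n
    records = [
        TrialRecord(
            trial_id=f"t{i}", condition=conditions[i], outcome=outcomes[i],
            covariates=covariates[i],
        )
        for i in range(n)
    ]
    return PopulationSession(
        responses=responses,
        modality=modality,
        trial_records=records,
        neuron_ids=[f"n{j}" for j in range(responses.shape[1])],
    )


@pytest.fixture
def two_condition_session():
    """Small continuous session with clearly separated condition patterns."""
    rng = np.random.default_rng(7)
    mu_a = np.array([1.0, 3.0, 5.0, 2.0, 4.0])
    mu_b = np.array([5.0, 2.0, 1.0, 4.0, 3.0])
    rows, conds, outs = [], [], []
    for i in range(12):
        mu = mu_a if i % 2 == 0 else mu_b
        rows.append(mu + rng.normal(0, 0.3, 5))
        conds.append("A" if i % 2 == 0 else "B")
        outs.append("hit" if i < 8 else "miss")
    return make_session(np.array(rows), conds, outs)


@pytest.fixture
def counts_session():
    """Small counts session drawn around two rate profiles."""
    rng = np.random.default_rng(11)
    lam_a = np.array([8.0, 2.0, 5.0, 1.0])
    lam_b = np.array([2.0, 8.0, 1.0, 5.0])
    rows, conds, outs = [], [], []
    for i in range(16):
        lam = lam_a if i % 2 == 0 else lam_b
        rows.append(rng.poisson(lam))
        conds.append("left" if i % 2 == 0 else "right")
        outs.append("hit" if i % 3 else "miss")
    return make_session(np.array(rows), conds, outs, modality="counts")
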