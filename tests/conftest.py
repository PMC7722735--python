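import numpy as np
import pandas as pd
import pytest

from bayescoin import (
    ConditionParams,
    ObserverSpec,
    cohort_frame,
    generate_session,
    simulate_cohort,
    simulate_observer,
)


@pytest.fixture(scope="session")
def default_params():
    return ConditionParams()


@pytest.fixture(scope="session")
def stimulus_session():
    """One full-design session of stimuli, no responses."""
    return generate_session(seed=11)


@pytest.fixture(scope="session")
def noiseless_bayes_session(stimulus_session):
    """Normative observer (subjective variances = imposed), zero motor noise."""
    spec = ObserverSpec(response_noise_sd=0.0)
    return simulate_observer(stimulus_session, spec, seed=12)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """10 participants (5/5), 160 trials each, moderate motor noise."""
    sessions = simulate_cohort(
        5,
        5,
        ObserverSpec(response_noise_sd=0.05),
        seed=21,
        trials_per_block=40,
    )
    return cohort_frame(sessions)


@pytest.fixture(scope="session")
def anova_fixture():
    """Balanced 3+3 condition-weight table with frozen split-plot oracle
    values (computed once with R's aov on this exact table)."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(6):
        g = "control" if i < 3 else "stressed"
        base = rng.normal(0.6, 0.1)
        w = {
            "pl": base + 0.05 + rng.normal(0, 0.05),
            "pL": base - 0.15 + rng.normal(0, 0.05),
            "Pl": base + 0.25 + rng.normal(0, 0.05),
            "PL": base + 0.10 + rng.normal(0, 0.05),
        }
        rows.append({"participant_id": f"p{i}", "group": g, **{f"weight_{c}": v for c, v in w.items()}})
    return pd.DataFrame(rows)
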