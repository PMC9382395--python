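import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def reduced_study():
    """Summaries of the reduced-replication simulation study.

    Computed once per session (this is the expensive part of the suite:
    12 scenario cells x 200 replicates, common 50,000-row test sets) and
    shared by the tests that check the study's headline findings.
    """
    from imbcal.engine import run_reduced_study, summarize_to_table

    summaries = run_reduced_study(base_seed=0, n_reps=200, n_test=50_000)
    return summaries, summarize_to_table(summaries)
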