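import pytest

from emibandit import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_log():
    """A compact simulated study log exercising every event type."""
    return simulate_cohort(SimParams(n_participants=4, n_days=10, seed=11))
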