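import pytest

from dynconn import StateModel, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 subjects, 6 regions, one strongly connected pair in both groups."""
    model = StateModel(n_regions=6, base_corr=0.9, pair_state_fraction={(0, 1): 0.8})
    return simulate_cohort(8, 8, model, length_tr=80, seed=11)
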