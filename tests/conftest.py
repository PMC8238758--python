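import numpy as np
import pytest
from hypothesis import settings

from memroc import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: criteria used throughout the tests (conservative placement, B = 6)
CRITERIA = (-0.5, 0.2, 0.85, 1.5, 2.2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_experiment():
    """A small DPSD experiment: 8 subjects, 60 old + 60 foils each."""
    design = synthetic.SimDesign(n_subjects=8, n_old=60, n_new=60)
    pop = synthetic.default_observer_population(8, model="DPSD", master_seed=99)
    return synthetic.simulate_experiment(design, pop, master_seed=99)


@pytest.fixture(scope="session")
def exp2_experiment():
    """An Exp-2-sized DPSD experiment: 42 subjects, 180 + 180 trials."""
    design = synthetic.exp2_design(42)
    pop = synthetic.default_observer_population(42, model="DPSD", master_seed=7)
    return synthetic.simulate_experiment(design, pop, master_seed=7)
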