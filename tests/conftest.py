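import numpy as np
import pandas as pd
import pytest

import aaci


@pytest.fixture(scope="session")
def pattern():
    return aaci.load_pattern()


@pytest.fixture(scope="session")
def ratios(pattern):
    return aaci.compute_beta_ratios(pattern)


@pytest.fixture(scope="session")
def sim_cohort():
    """One moderately sized simulated cohort shared across statistics tests."""
    cohort, truth = aaci.simulate_cohort(aaci.SimulationConfig(n_subjects=4000, seed=42))
    cohort, cuts = aaci.score_and_cut(cohort, cohort["aaci"])
    return cohort, truth, cuts


def random_intakes(rng, n, pattern, scale=0.4):
    """Random positive intake profiles (not pattern-proportional)."""
    base = np.array([pattern.levels[aa] for aa in aaci.SCORED_AAS])
    k = rng.uniform(20, 120, n)
    noise = np.exp(rng.normal(0, scale, (n, len(aaci.SCORED_AAS))))
    return pd.DataFrame(
        k[:, None] * base[None, :] * noise, columns=list(aaci.SCORED_AAS)
    )
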