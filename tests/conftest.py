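import numpy as np
import pytest

from critweight import StarvationRecord, SyntheticConfig, simulate_growth, \
    simulate_starvation_cohort
from critweight.growth import fit_growth_curve


@pytest.fixture(scope="session")
def exact_piecewise_records():
    """Noise-free hinge: y = 50 - 2x below the 8-hr break, 34 after; 3 larvae/age."""
    recs = []
    k = 0
    for age in np.arange(0, 22, 2.0):
        y = 50.0 - 2.0 * age if age <= 8 else 34.0
        for _ in range(3):
            recs.append(StarvationRecord(f"L{k}", "wt", float(age), y))
            k += 1
    return recs


@pytest.fixture(scope="session")
def wt_config():
    """Default synthetic wild-type-like cohort configuration."""
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def wt_cohort(wt_config):
    return simulate_starvation_cohort(wt_config, "wt")


@pytest.fixture(scope="session")
def wt_growth_fit(wt_config):
    return fit_growth_curve(simulate_growth(wt_config, "wt"))
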