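import numpy as np
import pytest

from rsvp_screen import cohort as ch

# Published confusion matrices (CI positive class): method -> (tp, fn, fp, tn)
PRINTED_CONFUSIONS = {
    "CDT": (6, 7, 2, 7),
    "Phototest": (5, 8, 0, 9),
    "Sequential": (7, 6, 2, 7),
    "RSVP (AM)": (7, 6, 1, 8),
    "RSVP (LR)": (12, 1, 1, 8),
}

# Published classification report: method -> (macro precision, macro recall,
# accuracy, 95% CI low, 95% CI high)
PRINTED_REPORT = {
    "CDT": (0.62, 0.62, 0.59, 0.39, 0.77),
    "Phototest": (0.76, 0.69, 0.64, 0.43, 0.80),
    "Sequential": (0.66, 0.66, 0.64, 0.43, 0.80),
    "RSVP (AM)": (0.72, 0.71, 0.68, 0.47, 0.84),
    "RSVP (LR)": (0.91, 0.91, 0.91, 0.72, 0.97),
}

# Published group comparison: test -> (reported U, effect size) at n=13 vs 9.
PRINTED_EFFECT_SIZES = {
    "CDT": (42.5, 0.64),
    "Phototest": (16.0, 0.86),
    "RSVP (global AM)": (21.0, 0.82),
    "RSVP (global AB)": (40.0, 0.66),
}


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default-calibration cohort (13 CI + 9 HC, 70 trials each)."""
    return ch.simulate_cohort(ch.CohortConfig(seed=8))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
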