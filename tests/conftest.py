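import numpy as np
import pandas as pd
import pytest

from isend.cohort import records_to_frame
from isend.score import score_record
from isend.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def pooled_cohort_5k():
    """Synthetic pooled-like cohort, n=5000, study-default censoring."""
    return generate_cohort(SimConfig(n=5000, seed=101))


@pytest.fixture(scope="session")
def pooled_frame_5k(pooled_cohort_5k):
    frame = records_to_frame(pooled_cohort_5k)
    frame["isend_group"] = [score_record(r).group for r in pooled_cohort_5k]
    frame["dnlr"] = frame["nlr2"] - frame["nlr1"]
    return frame


@pytest.fixture(scope="session")
def extended_followup_5k():
    """Same generator with administrative cutoff pushed out, so late medians
    (Good ~23 months) are estimable for parameter-recovery checks."""
    recs = generate_cohort(SimConfig(n=5000, seed=202, admin_cutoff_months=60.0))
    frame = records_to_frame(recs)
    frame["isend_group"] = [score_record(r).group for r in recs]
    return frame


def exponential_group_frame(rng, n_a, n_b, med_a, med_b,
                            cens_low=10.0, cens_high=26.0):
    """Two marker groups with exponential OS and uniform censoring."""
    n = n_a + n_b
    med = np.r_[np.full(n_a, med_a), np.full(n_b, med_b)]
    t_true = rng.exponential(med / np.log(2))
    cens = rng.uniform(cens_low, cens_high, n)
    return pd.DataFrame({
        "os_time": np.minimum(t_true, cens),
        "os_event": (t_true <= cens).astype(int),
        "grp": np.r_[np.full(n_a, "a"), np.full(n_b, "b")],
    })
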