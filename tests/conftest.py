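import numpy as np
import pandas as pd
import pytest


def make_interval_rows(subjects):
    """Counting-process rows from (patient_id, x, end_month, has_event) tuples.

    The covariate ``cd_status`` is held constant over the subject's intervals;
    ``age`` is zero so single-covariate fits are unaffected by it.
    """
    rows = []
    for pid, x, end, ev in subjects:
        for start in range(3, end, 3):
            rows.append({"patient_id": pid, "start": start, "stop": start + 3,
                         "event": int(ev and start + 3 == end),
                         "cd_status": x, "age": 0.0})
    return pd.DataFrame(rows)


@pytest.fixture
def interval_rows():
    return make_interval_rows


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_toy_dataset(rng, n_max=6):
    """A random small counting-process dataset with at least one event."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        subs = [(f"S{i}", int(rng.integers(0, 2)),
                 int(rng.choice([6, 9, 12, 15])), bool(rng.random() < 0.6))
                for i in range(n)]
        data = make_interval_rows(subs)
        if data["event"].sum() == 0:
            continue
        # informative only if, at some event time, the covariate varies within
        # the risk set and not every at-risk subject fails
        ok = False
        for t in data.loc[data["event"] == 1, "stop"].unique():
            at_risk = data[data["stop"] == t]
            if (at_risk["cd_status"].nunique() > 1
                    and at_risk["event"].sum() < len(at_risk)):
                ok = True
        if ok:
            return data
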