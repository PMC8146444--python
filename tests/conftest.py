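import numpy as np
import pandas as pd
import pytest

from herdaffinity import ScoringSpec, SyntheticConfig, generate_herd
from herdaffinity.scoring import AffinityNetwork

T0 = pd.Timestamp("2019-02-04")


def make_events(cow_seq, gap_seconds=60.0, pen_id="pen1", start=T0, times=None):
    """Build a one-pen gate-event frame from a cow sequence."""
    if times is None:
        times = np.arange(len(cow_seq)) * gap_seconds
    ts = start + pd.to_timedelta(np.asarray(times, dtype=float), unit="s")
    return pd.DataFrame(
        {
            "timestamp": ts.floor("s") if hasattr(ts, "floor") else ts,
            "cow_id": list(cow_seq),
            "pen_id": pen_id,
            "destination": "feeding",
        }
    )


def net_from_edges(edges, cows=None, pen_id="pen1", spec=None):
    """AffinityNetwork from a dict {(a, b): score}."""
    if cows is None:
        cows = sorted({c for e in edges for c in e})
    idx = {c: i for i, c in enumerate(cows)}
    w = np.zeros((len(cows), len(cows)))
    for (a, b), s in edges.items():
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = s
    return AffinityNetwork(pen_id, list(cows), w, spec or ScoringSpec(apply_month_weights=False, apply_residency_norm=False))


def make_residency(rows):
    """Residency frame from (cow, pen, entry_day, exit_day) day offsets."""
    return pd.DataFrame(
        {
            "cow_id": [r[0] for r in rows],
            "pen_id": [r[1] for r in rows],
            "entry_date": [T0 + pd.Timedelta(days=r[2]) for r in rows],
            "exit_date": [T0 + pd.Timedelta(days=r[3]) for r in rows],
        }
    )


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_pens=2, cows_per_pen=16, study_days=120, follow_prob=0.9, seed=11)


@pytest.fixture(scope="session")
def small_herd(small_config):
    return generate_herd(small_config)
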