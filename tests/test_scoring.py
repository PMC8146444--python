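"""Affinity-scoring unit and property tests against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdaffinity import ScoringSpec, month_weights, normalize_by_residency
from herdaffinity.scoring import score_inverse_interval, score_lag_sequence, score_window

from conftest import make_events, make_residency, net_from_edges
from _oracles import network_to_pair_scores, oracle_inverse, oracle_lag, oracle_window

RAW = ScoringSpec(apply_month_weights=False, apply_residency_norm=False)


def _random_pen(rng, n_events, n_cows, span_hours=6.0):
    times = np.sort(rng.uniform(0, span_hours * 3600, n_events))
    cows = [f"C{i:02d}" for i in rng.integers(0, n_cows, n_events)]
    return times, cows


class TestLagSequence:
    def test_worked_example(self):
        """Order A,B,C,A with base 2: AB=1.5, AC=1.5, BC=1.0 exactly."""
        net = score_lag_sequence(make_events("ABCA"), RAW)
        assert net.score("A", "B") == pytest.approx(1.5)
        assert net.score("A", "C") == pytest.approx(1.5)
        assert net.score("B", "C") == pytest.approx(1.0)

    def test_single_cow_zero_matrix(self):
        net = score_lag_sequence(make_events("AAAA"), RAW)
        assert np.all(net.weights == 0)

    @pytest.mark.parametrize("n", [4, 7, 20])
    def test_alternating_closed_form(self, n):
        """A,B,A,B,...: lags 1 and 3 hit the partner, lags 2 and 4 hit self.

        With base 2 the pair score is (n-1)*1 + (n-3)*0.25, confirmed by the
        brute-force oracle.
        """
        seq = ("AB" * n)[:n]
        net = score_lag_sequence(make_events(seq), RAW)
        expected = (n - 1) * 1.0 + (n - 3) * 0.25
        assert net.score("A", "B") == pytest.approx(expected)
        assert oracle_lag(list(seq))[frozenset("AB")] == pytest.approx(expected)

    def test_unsorted_events_rejected(self):
        ev = make_events("ABC", times=[10.0, 5.0, 20.0])
        with pytest.raises(ValueError, match="sorted"):
            score_lag_sequence(ev, RAW)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=2, max_size=60), st.integers(1, 6))
    def test_matches_oracle(self, seq, max_lag):
        spec = ScoringSpec(max_lag=max_lag, apply_month_weights=False, apply_residency_norm=False)
        net = score_lag_sequence(make_events(seq), spec)
        oracle = oracle_lag(seq, max_lag=max_lag)
        assert network_to_pair_scores(net) == pytest.approx(oracle)

    def test_time_translation_invariance(self):
        """Pure order scoring: shifting all timestamps changes nothing."""
        rng = np.random.default_rng(0)
        times, cows = _random_pen(rng, 100, 6)
        a = score_lag_sequence(make_events(cows, times=times), RAW)
        b = score_lag_sequence(make_events(cows, times=times + 98765.0), RAW)
        assert np.allclose(a.weights, b.weights)


class TestWindow:
    def test_presence_not_count(self):
        """A and B each passing twice within one bin score a single unit."""
        ev = make_events("ABAB", times=[10, 20, 30, 40])
        net = score_window(ev, RAW)
        assert net.score("A", "B") == pytest.approx(1.0)

    def test_bin_boundary(self):
        """00:14 and 00:16 fall in different 15-min bins: no score."""
        ev = make_events("AB", times=[14 * 60, 16 * 60])
        net = score_window(ev, RAW)
        assert net.score("A", "B") == 0.0

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            times, cows = _random_pen(rng, int(rng.integers(2, 200)), 8)
            net = score_window(make_events(cows, times=times), RAW)
            oracle = oracle_window(times, cows)
            assert network_to_pair_scores(net) == pytest.approx(oracle)


class TestInverseInterval:
    def test_formula(self):
        ev = make_events("AB", times=[0.0, 10.0])
        assert score_inverse_interval(ev, RAW).score("A", "B") == pytest.approx(0.1)

    def test_epsilon_guard(self):
        ev = make_events("AB", times=[5.0, 5.0])
        assert score_inverse_interval(ev, RAW).score("A", "B") == pytest.approx(1.0)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            times, cows = _random_pen(rng, int(rng.integers(2, 200)), 8)
            times = np.floor(times)  # second resolution, as read from CSV
            net = score_inverse_interval(make_events(cows, times=times), RAW)
            oracle = oracle_inverse(times, cows)
            assert network_to_pair_scores(net) == pytest.approx(oracle)


class TestMonthWeights:
    def test_busiest_month_downweighted(self):
        """Busiest month weighted 2.8x less than the quietest."""
        counts = pd.DataFrame({"month": [3, 12], "count": [1000, 2800]})
        w = month_weights(counts)
        assert w[3] == pytest.approx(1.0)
        assert w[12] == pytest.approx(1 / 2.8)
        assert w[3] / w[12] == pytest.approx(2.8)

    def test_equal_counts(self):
        counts = pd.DataFrame({"month": range(1, 13), "count": [500] * 12})
        assert all(v == pytest.approx(1.0) for v in month_weights(counts).values())

    def test_zero_month_weight_zero_and_identity(self):
        counts = pd.DataFrame({"month": [1, 2, 3], "count": [200, 0, 800]})
        w = month_weights(counts)
        assert w[2] == 0.0
        # algebraic identity: w_min * C_max == w_max * C_min
        assert min(w[1], w[3]) * 800 == pytest.approx(max(w[1], w[3]) * 200)

    def test_weighted_lag_matches_oracle(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 90 * 86400, 150))  # spans ~3 months
        cows = [f"C{i}" for i in rng.integers(0, 5, 150)]
        ev = make_events(cows, times=times)
        counts = ev.groupby(ev["timestamp"].dt.month).size().rename("count").rename_axis("month").reset_index()
        mw = month_weights(counts)
        net = score_lag_sequence(ev, RAW, mw)
        ew = [mw[m] for m in ev["timestamp"].dt.month]
        oracle = oracle_lag(cows, event_weights=ew)
        assert network_to_pair_scores(net) == pytest.approx(oracle)


class TestResidencyNorm:
    def test_geometric_formula(self):
        net = net_from_edges({("A", "B"): 10.0})
        res = make_residency([("A", "pen1", 0, 99), ("B", "pen1", 0, 99)])
        out = normalize_by_residency(net, res)
        assert out.score("A", "B") == pytest.approx(0.1)

    def test_doubling_residency_halves_score(self):
        net = net_from_edges({("A", "B"): 10.0})
        short = make_residency([("A", "pen1", 0, 99), ("B", "pen1", 0, 99)])
        long = make_residency([("A", "pen1", 0, 199), ("B", "pen1", 0, 199)])
        s_short = normalize_by_residency(net, short).score("A", "B")
        s_long = normalize_by_residency(net, long).score("A", "B")
        assert s_long / s_short == pytest.approx(0.5)

    def test_shorter_tenure_ranks_higher(self):
        """Equal raw scores: the short-tenure pair outranks the long one."""
        net = net_from_edges({("A", "B"): 10.0, ("C", "D"): 10.0})
        res = make_residency(
            [("A", "pen1", 0, 49), ("B", "pen1", 0, 49), ("C", "pen1", 0, 299), ("D", "pen1", 0, 299)]
        )
        out = normalize_by_residency(net, res)
        assert out.score("A", "B") > out.score("C", "D")

    def test_zero_residency_errors(self):
        net = net_from_edges({("A", "B"): 1.0})
        res = make_residency([("A", "pen1", 0, 10)])
        with pytest.raises(ValueError, match="no residency"):
            normalize_by_residency(net, res)


class TestCrossMethodInvariants:
    def test_zero_pattern_agreement(self):
        """Cows that never co-occur within any window/lag score zero in all methods."""
        # A and B separated by >4 intervening events and by hours of time
        cows = list("AAAA") + list("CDEF") + list("BBBB")
        times = np.concatenate([np.arange(4) * 30.0, 1e6 + np.arange(4) * 30.0, 2e6 + np.arange(4) * 30.0])
        ev = make_events(cows, times=times)
        for scorer in (score_window, score_inverse_interval, score_lag_sequence):
            assert scorer(ev, RAW).score("A", "B") == 0.0

    def test_label_equivariance(self):
        """Permuting cow labels permutes the score matrix identically."""
        rng = np.random.default_rng(4)
        times, cows = _random_pen(rng, 80, 5)
        mapping = {"C00": "Z", "C01": "Y", "C02": "X", "C03": "W", "C04": "V"}
        net1 = score_lag_sequence(make_events(cows, times=times), RAW)
        net2 = score_lag_sequence(make_events([mapping[c] for c in cows], times=times), RAW)
        for i, a in enumerate(net1.cows):
            for j, b in enumerate(net1.cows):
                if a in mapping and b in mapping:
                    assert net1.weights[i, j] == pytest.approx(net2.score(mapping[a], mapping[b])) or a == b
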