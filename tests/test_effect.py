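"""Affinity-period labelling, deviation summaries and the per-pen tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from herdaffinity import dim_balance_check, holm_adjust, label_periods, pen_paired_test, summarize_deviation
from herdaffinity.synthetic import simulate_labelled_residuals

from conftest import T0, make_residency


def pair_frame(*pairs, pen="pen1"):
    return pd.DataFrame(
        {"pen_id": pen, "cow_a": [a for a, _ in pairs], "cow_b": [b for _, b in pairs]}
    )


def resid_frame(cow, values, start_day=0, pen="pen1", dim0=50):
    days = np.arange(len(values))
    return pd.DataFrame(
        {
            "cow_id": cow,
            "pen_id": pen,
            "date": T0 + pd.to_timedelta(start_day + days, unit="D"),
            "dim": dim0 + days,
            "residual_kg": np.asarray(values, dtype=float),
        }
    )


class TestLabelPeriods:
    def test_partner_exit_splits_periods(self):
        """Partner leaves at day 200 of 300: 200 affinity + 100 broken days."""
        res = make_residency([("A", "pen1", 0, 299), ("B", "pen1", 0, 199)])
        lab = label_periods(pair_frame(("A", "B")), res)
        a = lab[lab["cow_id"] == "A"]
        assert (a["label"] == "affinity").sum() == 200
        assert (a["label"] == "broken").sum() == 100
        # day conservation: labels cover exactly A's resident days
        assert len(a) == 300

    def test_coresident_all_period(self):
        res = make_residency([("A", "pen1", 0, 364), ("B", "pen1", 0, 364)])
        lab = label_periods(pair_frame(("A", "B")), res)
        assert set(lab["label"]) == {"affinity"}

    def test_pen_move_breaks_affinity(self):
        """Both resident but in different pens counts as broken."""
        res = make_residency([("A", "pen1", 0, 99), ("B", "pen1", 0, 49), ("B", "pen2", 50, 99)])
        lab = label_periods(pair_frame(("A", "B")), res)
        a = lab[lab["cow_id"] == "A"]
        assert (a["label"] == "affinity").sum() == 50
        assert (a["label"] == "broken").sum() == 50

    def test_exact_agreement_with_ground_truth(self, small_herd):
        """Given true residency and the planted pairs, labels match the
        generator's own period labels exactly."""
        truth = small_herd.truth
        pairs = pd.DataFrame(
            [(pen, a, b) for pen, ps in truth.planted_pairs.items() for a, b in ps],
            columns=["pen_id", "cow_a", "cow_b"],
        )
        lab = label_periods(pairs, small_herd.residency)
        merged = lab.merge(truth.labels, on=["cow_id", "date"], suffixes=("", "_truth"))
        assert len(merged) == len(lab)
        assert (merged["label"] == merged["label_truth"]).all()


class TestSummaries:
    def test_hand_arithmetic(self):
        rf = pd.concat(
            [resid_frame("A", [1.0, -1.0] * 5), resid_frame("B", [0.5] * 8)], ignore_index=True
        )
        periods = rf.assign(label="affinity")[["cow_id", "date", "label"]]
        out = summarize_deviation(rf, periods, min_period_days=7)
        a = out[out["cow_id"] == "A"].iloc[0]
        assert a["mean_dev"] == pytest.approx(0.0)
        assert a["sd_dev"] == pytest.approx(np.sqrt(10 / 9), rel=1e-6)  # sample SD of +/-1
        b = out[out["cow_id"] == "B"].iloc[0]
        assert b["mean_dev"] == pytest.approx(0.5)
        assert b["sd_dev"] == pytest.approx(0.0)

    def test_min_period_days_suppression(self):
        rf = resid_frame("A", [1.0] * 6)
        periods = rf.assign(label="broken")[["cow_id", "date", "label"]]
        assert summarize_deviation(rf, periods, min_period_days=7).empty


class TestHolm:
    def test_hand_computed_example(self):
        adj = holm_adjust([0.008, 0.9, 0.6, 0.7])
        assert adj == pytest.approx([0.032, 1.0, 1.0, 1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_dominates_raw_and_bounded_by_bonferroni(self, ps):
        adj = holm_adjust(ps)
        ps = np.asarray(ps)
        assert (adj >= ps - 1e-12).all()
        assert (adj <= np.minimum(ps * len(ps), 1.0) + 1e-12).all()
        # monotone: order of adjusted follows order of raw
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPenPairedTest:
    def _panel(self, rng, shift=0.3, sd_a=0.8, sd_b=2.6, n_cows=20, n_days=200):
        return simulate_labelled_residuals(n_cows, n_days, sd_a, sd_b, -shift, rng)

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(7)
        out = pen_paired_test(self._panel(rng, shift=0.8))
        pen = out[out["pen_id"] == "pen1"].iloc[0]
        assert pen["testable"]
        assert pen["mean_diff"] > 0
        assert pen["p_raw"] < 0.05
        assert pen["p_holm"] >= pen["p_raw"]

    def test_degenerate_identical_diffs_flagged(self):
        rf = pd.concat(
            [resid_frame("A", [0.0] * 30), resid_frame("B", [0.0] * 30)], ignore_index=True
        )
        rf["label"] = np.where(rf.groupby("cow_id").cumcount() < 15, "affinity", "broken")
        out = pen_paired_test(rf)
        pen = out[out["pen_id"] == "pen1"].iloc[0]
        assert not pen["testable"]
        assert np.isnan(pen["p_raw"])

    def test_single_cow_not_testable(self):
        rng = np.random.default_rng(8)
        out = pen_paired_test(self._panel(rng, n_cows=1))
        assert not out[out["pen_id"] == "pen1"]["testable"].iloc[0]

    def test_overall_row_pools_without_test(self):
        rng = np.random.default_rng(9)
        out = pen_paired_test(self._panel(rng))
        overall = out[out["pen_id"] == "Overall"].iloc[0]
        assert np.isnan(overall["p_raw"]) and np.isnan(overall["p_holm"])
        assert overall["sd_broken"] > overall["sd_affinity"]

    def test_power_against_strong_shift(self):
        """-0.6 kg/day shift, 25 pairs: rejects at alpha=.05 in >=80% of reps."""
        hits = 0
        n_reps = 40  # scaled down from 100 for suite runtime; same world
        for seed in range(n_reps):
            rng = np.random.default_rng(20_000 + seed)
            out = pen_paired_test(self._panel(rng, shift=0.6, n_cows=25))
            hits += out[out["pen_id"] == "pen1"]["p_raw"].iloc[0] < 0.05
        assert hits / n_reps >= 0.8


class TestDimBalance:
    def test_identical_dim_sets(self):
        rf = resid_frame("A", np.zeros(40))
        rf["label"] = ["affinity", "broken"] * 20  # interleaved: same DIM spread
        out = dim_balance_check(rf)
        assert out["ks_statistic"] < 0.1

    def test_disjoint_dim_ranges(self):
        rf = resid_frame("A", np.zeros(40))
        rf["label"] = ["affinity"] * 20 + ["broken"] * 20
        out = dim_balance_check(rf)
        assert out["ks_statistic"] == pytest.approx(1.0)

    def test_requires_both_types(self):
        rf = resid_frame("A", np.zeros(10)).assign(label="affinity")
        with pytest.raises(ValueError):
            dim_balance_check(rf)
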