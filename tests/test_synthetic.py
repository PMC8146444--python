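"""Generator contract tests: determinism, consistency, planted signals."""

import numpy as np
import pandas as pd
import pytest

from herdaffinity import ResidencyModel, SyntheticConfig, generate_herd, write_fixture
from herdaffinity.lactation import wood


class TestConfigValidation:
    def test_zero_study_days_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(study_days=0)

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(follow_prob=1.5)

    def test_odd_pairable_count_warns(self):
        cfg = SyntheticConfig(cows_per_pen=54, affinity_fraction=0.5)
        with pytest.warns(UserWarning, match="even"):
            assert cfg.n_paired_per_pen == 26


class TestDeterminism:
    def test_identical_config_identical_outputs(self):
        cfg = SyntheticConfig(n_pens=1, cows_per_pen=10, study_days=40, affinity_fraction=0.4, seed=5)
        h1, h2 = generate_herd(cfg), generate_herd(cfg)
        pd.testing.assert_frame_equal(h1.gate_events, h2.gate_events)
        pd.testing.assert_frame_equal(h1.milk_records, h2.milk_records)
        pd.testing.assert_frame_equal(h1.residency, h2.residency)
        assert h1.truth.planted_pairs == h2.truth.planted_pairs

    def test_seed_changes_outputs(self):
        cfg1 = SyntheticConfig(n_pens=1, cows_per_pen=10, study_days=40, affinity_fraction=0.4, seed=5)
        cfg2 = SyntheticConfig(n_pens=1, cows_per_pen=10, study_days=40, affinity_fraction=0.4, seed=6)
        assert not generate_herd(cfg1).gate_events.equals(generate_herd(cfg2).gate_events)

    def test_fixture_files_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_pens=1, cows_per_pen=8, study_days=30, seed=2)
        p1 = write_fixture(generate_herd(cfg), tmp_path / "a")
        p2 = write_fixture(generate_herd(cfg), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()


class TestConsistency:
    def test_events_and_milk_within_residency(self, small_herd):
        res = small_herd.residency.set_index("cow_id")
        ev = small_herd.gate_events
        entry = ev["cow_id"].map(res["entry_date"])
        exit_ = ev["cow_id"].map(res["exit_date"]) + pd.Timedelta(days=1)
        assert ((ev["timestamp"] >= entry) & (ev["timestamp"] < exit_)).all()
        mk = small_herd.milk_records
        assert ((mk["date"] >= mk["cow_id"].map(res["entry_date"])) &
                (mk["date"] <= mk["cow_id"].map(res["exit_date"]))).all()

    def test_one_milk_record_per_cow_day_and_dim_steps(self, small_herd):
        mk = small_herd.milk_records
        assert not mk.duplicated(["cow_id", "date"]).any()
        for _, g in mk.groupby("cow_id"):
            g = g.sort_values("date")
            assert (g["dim"].diff().dropna() == g["date"].diff().dt.days.dropna()).all()

    def test_period_labels_consistent_with_residency(self, small_herd):
        truth = small_herd.truth
        res = small_herd.residency.set_index("cow_id")
        partners = {}
        for pairs in truth.planted_pairs.values():
            for a, b in pairs:
                partners[a], partners[b] = b, a
        lab = truth.labels[truth.labels["cow_id"].isin(partners)]
        mate_exit = lab["cow_id"].map(lambda c: res.loc[partners[c], "exit_date"])
        mate_entry = lab["cow_id"].map(lambda c: res.loc[partners[c], "entry_date"])
        co = (lab["date"] >= mate_entry) & (lab["date"] <= mate_exit)
        assert (lab["label"].eq("affinity") == co).all()


class TestPlantedSignals:
    def test_follow_prob_one_every_event_has_partner_nearby(self):
        cfg = SyntheticConfig(
            n_pens=1, cows_per_pen=8, study_days=30, affinity_fraction=1.0,
            follow_prob=1.0, seed=3,
        )
        herd = generate_herd(cfg)
        ev = herd.gate_events
        gap = cfg.follow_gap_seconds
        ok = total = 0
        for _, a, b in herd.truth.all_pairs():
            ta = ev.loc[ev["cow_id"] == a, "timestamp"].astype("int64").to_numpy() // 10**9
            tb = ev.loc[ev["cow_id"] == b, "timestamp"].astype("int64").to_numpy() // 10**9
            for times, other in ((ta, tb), (tb, ta)):
                idx = np.searchsorted(other, times)
                near = np.zeros(len(times), dtype=bool)
                for off in (-1, 0, 1):
                    j = np.clip(idx + off, 0, len(other) - 1)
                    near |= np.abs(other[j] - times) <= gap + 1
                ok += near.sum()
                total += len(times)
        assert ok / total >= 0.99

    def test_follow_prob_zero_no_timing_signal(self):
        """Independent streams: planted pairs score no better than median."""
        from herdaffinity.scoring import ScoringSpec, score_lag_sequence

        cfg = SyntheticConfig(
            n_pens=1, cows_per_pen=16, study_days=90, affinity_fraction=0.5,
            follow_prob=0.0, seed=4,
            residency_model=ResidencyModel(fraction_day0=1.0),
        )
        herd = generate_herd(cfg)
        net = score_lag_sequence(
            herd.gate_events, ScoringSpec(apply_month_weights=False, apply_residency_norm=False)
        )
        iu, ju = np.triu_indices(net.n_cows, 1)
        median = np.median(net.weights[iu, ju])
        planted = [net.score(a, b) for _, a, b in herd.truth.all_pairs()]
        # at chance, ~half of planted pairs sit below the median score
        below = sum(s <= median for s in planted)
        assert below >= len(planted) * 0.25

    def test_mean_passes_near_configured_rate(self, small_herd, small_config):
        ev, res = small_herd.gate_events, small_herd.residency
        days = ((res["exit_date"] - res["entry_date"]).dt.days + 1).groupby(res["cow_id"]).sum()
        per = ev.groupby("cow_id").size() / days
        assert per.mean() == pytest.approx(small_config.passes_per_cow_day, abs=0.5)

    def test_planted_sd_ratio_recoverable_from_true_curve(self):
        """With no mean shift, residuals about the true curves reproduce
        sd_broken/sd_affinity (40 cows x >=100 days)."""
        cfg = SyntheticConfig(
            n_pens=1, cows_per_pen=40, study_days=200, affinity_fraction=1.0,
            mean_shift_broken=0.0, seed=6,
            residency_model=ResidencyModel(fraction_day0=1.0),
        )
        herd = generate_herd(cfg)
        tp = herd.truth.wood_params[["cow_id", "alpha", "beta", "gamma"]]
        mk = herd.milk_records.merge(tp, on="cow_id")
        mk["resid"] = mk["yield_kg"] - mk["alpha"] * np.power(mk["dim"].astype(float), mk["beta"]) * np.exp(-mk["gamma"] * mk["dim"])
        lab = mk.merge(herd.truth.labels[["cow_id", "date", "label"]], on=["cow_id", "date"])
        sd = lab.groupby("label")["resid"].std()
        ratio = sd["broken"] / sd["affinity"]
        assert ratio == pytest.approx(cfg.sd_broken / cfg.sd_affinity, rel=0.15)

    def test_milk_follows_wood_curve_plus_noise(self, small_herd):
        tp = small_herd.truth.wood_params.set_index("cow_id")
        mk = small_herd.milk_records
        cow = tp.index[0]
        g = mk[mk["cow_id"] == cow]
        mu = wood(g["dim"].to_numpy(float), tp.loc[cow, "alpha"], tp.loc[cow, "beta"], tp.loc[cow, "gamma"])
        resid = g["yield_kg"].to_numpy() - mu
        assert np.abs(resid).max() < 15  # noise-scale, not curve-scale, errors
        assert np.std(resid) < 3.5


class TestFixtureRoundTrip:
    def test_header_only_for_no_events(self, tmp_path):
        # a 1-day herd with a minuscule pass rate can produce zero events
        cfg = SyntheticConfig(
            n_pens=1, cows_per_pen=1, study_days=1, passes_per_cow_day=1e-9,
            affinity_fraction=0.0, seed=0,
        )
        herd = generate_herd(cfg)
        paths = write_fixture(herd, tmp_path)
        text = paths["gate_events"].read_text()
        assert text.splitlines()[0] == "timestamp,cow_id,pen_id,destination"

    def test_roundtrip_reproduces_tables(self, tmp_path, small_herd):
        from herdaffinity import read_gate_events, read_milk_records, read_residency

        paths = write_fixture(small_herd, tmp_path)
        ev = read_gate_events(paths["gate_events"])
        mk = read_milk_records(paths["milk_records"])
        res = read_residency(paths["residency"])
        pd.testing.assert_frame_equal(ev, small_herd.gate_events, check_dtype=False)
        pd.testing.assert_frame_equal(
            mk.sort_values(["cow_id", "date"]).reset_index(drop=True),
            small_herd.milk_records.sort_values(["cow_id", "date"]).reset_index(drop=True)[mk.columns],
            check_dtype=False,
        )
        assert len(res) == len(small_herd.residency)
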