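"""Synthetic AMS herd generator with planted ground truth.

Emulates a guided-flow robotic-milking farm: several pens of ~54 cows, each
passing the pen's sorting gate about 10 times a day over a year, with
dynamic residency (cows enter and leave for management reasons), per-cow
Wood lactation curves, and *planted affinity pairs* — pairs of cows that
pass the gate in close succession.  Because every pair, parameter and
period label is known, every downstream stage (scoring, matching, fitting,
the affinity contrast) can be verified against ground truth.

Mechanics of the planted signals:

* A planted pair shares an entry day; one mate leaves earlier, so the
  remaining mate has an ``affinity`` period (partner co-resident) followed
  by a ``broken`` tail.
* On co-resident days one mate's passages trigger, with probability
  ``follow_prob``, a partner passage within ``follow_gap_seconds``.  The
  follower's own spontaneous traffic is thinned by the same probability so
  every cow's total passage rate stays at the configured mean — the follow
  signal changes *timing*, not traffic volume.
* Daily milk yield is the cow's Wood curve plus Gaussian noise whose SD
  (and mean shift) depends on the day's period label: calm, low-SD noise
  while the pair is intact; inflated SD and a (usually negative) mean shift
  after it breaks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lactation import wood

__all__ = [
    "WoodParamDists",
    "ResidencyModel",
    "SyntheticConfig",
    "GroundTruth",
    "HerdData",
    "generate_herd",
    "write_fixture",
    "simulate_labelled_residuals",
]

SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class WoodParamDists:
    """Sampling distributions for per-cow Wood parameters.

    Defaults give realistic curves peaking near 37-40 kg around DIM 60,
    matching typical per-pen daily means of 36-42 kg: alpha is lognormal
    around 17, beta normal(0.25, 0.05) truncated above 0.05, gamma
    normal(0.004, 0.001) truncated above 0.0005.
    """

    alpha_log_mean: float = float(np.log(17.0))
    alpha_log_sd: float = 0.2
    beta_mean: float = 0.25
    beta_sd: float = 0.05
    beta_min: float = 0.05
    gamma_mean: float = 0.004
    gamma_sd: float = 0.001
    gamma_min: float = 0.0005

    def sample(self, rng: np.random.Generator, n: int):
        alpha = np.exp(rng.normal(self.alpha_log_mean, self.alpha_log_sd, n))
        beta = rng.normal(self.beta_mean, self.beta_sd, n)
        gamma = rng.normal(self.gamma_mean, self.gamma_sd, n)
        # truncate by redrawing (bounded loop; the tails are tiny)
        for _ in range(100):
            bad_b = beta <= self.beta_min
            bad_g = gamma <= self.gamma_min
            if not (bad_b.any() or bad_g.any()):
                break
            beta[bad_b] = rng.normal(self.beta_mean, self.beta_sd, int(bad_b.sum()))
            gamma[bad_g] = rng.normal(self.gamma_mean, self.gamma_sd, int(bad_g.sum()))
        beta = np.maximum(beta, self.beta_min)
        gamma = np.maximum(gamma, self.gamma_min)
        return alpha, beta, gamma


@dataclass(frozen=True)
class ResidencyModel:
    """Stay-length and turnover model for the pen roster.

    The pen is modelled as a fixed set of slots kept full by renewal: when
    a stay ends, a new cow (or pair) takes the slot the next day, so the
    concurrent pen size stays near capacity while unique cows accumulate
    over the year.  Stay durations follow the four observed residency bands
    (30-90, 91-180, 181-270, >271 days) weighted by their pooled cow
    counts; the first tenant of each slot starts mid-stay (stationary age)
    unless pinned to a fresh day-0 start via ``fraction_day0``.  Planted
    pairs are broken by pulling one mate's exit earlier by
    ``break_min_days``-``break_max_days`` days, but never below
    ``min_affinity_days`` of co-residence — a pair whose whole stay is that
    short simply never breaks.  ``short_stay_fraction`` plants single cows
    below the 30-day analysis filter.
    """

    fraction_day0: float = 0.0
    duration_bands: tuple = ((30, 90), (91, 180), (181, 270), (271, 365))
    band_weights: tuple = (124, 99, 149, 66)
    short_stay_fraction: float = 0.0
    short_stay_days: tuple = (5, 29)
    break_min_days: int = 30
    break_max_days: int = 120
    min_affinity_days: int = 60

    def sample_duration(self, rng: np.random.Generator) -> int:
        w = np.asarray(self.band_weights, dtype=float)
        band = self.duration_bands[rng.choice(len(self.duration_bands), p=w / w.sum())]
        return int(rng.integers(band[0], band[1] + 1))



@dataclass(frozen=True)
class SyntheticConfig:
    """The stated world of the synthetic farm.

    Defaults follow the farm the pipeline emulates: 4 pens averaging 54
    concurrent cows (``cows_per_pen`` is pen *capacity*; with turnover,
    roughly twice that many unique cows pass through over a year) over 365
    days, ~10 gate passages/cow/day of which ~27% divert to milking (2.7
    milkings/day), and period noise SDs of 0.8 kg/day (affinity) vs 2.6
    kg/day (broken) with a -0.3 kg/day broken-period mean shift.
    """

    n_pens: int = 4
    cows_per_pen: int = 54
    study_days: int = 365
    passes_per_cow_day: float = 10.0
    milking_fraction: float = 0.27
    affinity_fraction: float = 0.5
    follow_prob: float = 0.8
    follow_gap_seconds: float = 30.0
    residency_model: ResidencyModel = field(default_factory=ResidencyModel)
    wood_param_dists: WoodParamDists = field(default_factory=WoodParamDists)
    sd_affinity: float = 0.8
    sd_broken: float = 2.6
    mean_shift_broken: float = -0.3
    start_date: str = "2019-02-04"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pens, self.cows_per_pen) < 1:
            raise ValueError("counts must be >= 1")
        if self.study_days < 1:
            raise ValueError("study_days must be >= 1")
        if not (0 <= self.affinity_fraction <= 1 and 0 <= self.follow_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.passes_per_cow_day <= 0 or self.follow_gap_seconds <= 0:
            raise ValueError("rates and durations must be positive")
        if self.sd_affinity <= 0 or self.sd_broken <= 0:
            raise ValueError("noise SDs must be positive")

    @property
    def n_paired_per_pen(self) -> int:
        n = int(self.affinity_fraction * self.cows_per_pen)
        if n % 2:
            warnings.warn("affinity_fraction x cows_per_pen is odd; rounding down to an even pair count")
        return n - (n % 2)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    planted_pairs: dict[str, list[tuple[str, str]]]
    wood_params: pd.DataFrame  # cow_id, pen_id, lactation_number, alpha, beta, gamma, dim0
    residency: pd.DataFrame
    labels: pd.DataFrame  # cow_id, date, label in {affinity, broken, unpaired}
    config: SyntheticConfig

    def all_pairs(self) -> list[tuple[str, str, str]]:
        return [(pen, a, b) for pen, pairs in self.planted_pairs.items() for a, b in pairs]


@dataclass
class HerdData:
    gate_events: pd.DataFrame
    milk_records: pd.DataFrame
    residency: pd.DataFrame
    truth: GroundTruth


def _spontaneous_events(rng, days: np.ndarray, rate: float) -> np.ndarray:
    """Event times (seconds from study start) for independent daily Poisson traffic."""
    counts = rng.poisson(rate, len(days))
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    day_of = np.repeat(days, counts)
    return day_of * SECONDS_PER_DAY + rng.uniform(0.0, SECONDS_PER_DAY, total)


def generate_herd(config: SyntheticConfig) -> HerdData:
    """Generate gate events, milk records, residency and ground truth.

    Identical configs (including the seed) produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    rm = config.residency_model
    start = pd.Timestamp(config.start_date)
    D = config.study_days
    rate = config.passes_per_cow_day

    ev_rows = {"t": [], "cow": [], "pen": []}
    milk_rows = []
    res_rows = []
    truth_pairs: dict[str, list[tuple[str, str]]] = {}
    param_rows = []
    label_rows = []

    for pen_i in range(1, config.n_pens + 1):
        pen = f"pen{pen_i}"
        n_pair_slots = config.n_paired_per_pen // 2
        n_single_slots = config.cows_per_pen - 2 * n_pair_slots
        counter = [0]

        def new_cow() -> str:
            counter[0] += 1
            return f"P{pen_i}C{counter[0]:03d}"

        # residency: a slot/renewal roster keeps the pen near its capacity.
        # Each slot hosts a succession of cows (or pairs); the first tenant
        # gets a stationary "age" so turnover is staggered, and stays are
        # censored at the study-window edges.
        entry: dict[str, int] = {}
        exit_: dict[str, int] = {}
        break_day: dict[str, int] = {}  # last co-resident day, per paired cow
        partner: dict[str, str] = {}
        roster: list[str] = []
        pairs: list[tuple[str, str]] = []

        for _ in range(n_single_slots):
            t: int | None = None
            while t is None or t < D:
                if rng.random() < rm.short_stay_fraction:
                    dur = int(rng.integers(rm.short_stay_days[0], rm.short_stay_days[1] + 1))
                else:
                    dur = rm.sample_duration(rng)
                if t is None:
                    t = 0 if rng.random() < rm.fraction_day0 else -int(rng.integers(0, dur))
                e, x = max(0, t), min(t + dur - 1, D - 1)
                if x >= e:
                    c = new_cow()
                    roster.append(c)
                    entry[c], exit_[c] = e, x
                t += dur

        for _ in range(n_pair_slots):
            t = None
            while t is None or t < D:
                dur = rm.sample_duration(rng)
                if t is None:
                    t = 0 if rng.random() < rm.fraction_day0 else -int(rng.integers(0, dur))
                e_long = t + dur - 1
                delta = int(rng.integers(rm.break_min_days, rm.break_max_days + 1))
                e_short = min(max(t + rm.min_affinity_days - 1, e_long - delta), e_long)
                ce = max(0, t)
                cel, ces = min(e_long, D - 1), min(e_short, D - 1)
                if cel >= ce:
                    c1, c2 = new_cow(), new_cow()
                    stayer, leaver = (c1, c2) if rng.random() < 0.5 else (c2, c1)
                    roster.extend([c1, c2])
                    if ces >= ce:
                        entry[stayer], exit_[stayer] = ce, cel
                        entry[leaver], exit_[leaver] = ce, ces
                        a, b = sorted((stayer, leaver))
                        pairs.append((a, b))
                        partner[a], partner[b] = b, a
                        break_day[a] = break_day[b] = ces
                    else:
                        # the leaver left before the window: the stayer is
                        # effectively a single cow within the study
                        entry[stayer], exit_[stayer] = ce, cel
                        roster.remove(c2 if stayer == c1 else c1)
                # next tenancy starts the day after the longer stay ends
                t = e_long + 2
        truth_pairs[pen] = sorted(pairs)

        for c in roster:
            res_rows.append((c, pen, entry[c], exit_[c]))

        # lactation parameters ------------------------------------------
        alpha, beta, gamma = config.wood_param_dists.sample(rng, len(roster))
        dim0 = rng.integers(1, 121, len(roster))
        lact = rng.choice([1, 2, 3], size=len(roster), p=[0.45, 0.35, 0.2])
        for c, a_, b_, g_, d0, ln in zip(roster, alpha, beta, gamma, dim0, lact):
            param_rows.append((c, pen, int(ln), float(a_), float(b_), float(g_), int(d0)))

        # per-day labels and milk ---------------------------------------
        for ci, c in enumerate(roster):
            days = np.arange(entry[c], exit_[c] + 1)
            if c in partner:
                labels = np.where(days <= break_day[c], "affinity", "broken")
            else:
                labels = np.full(len(days), "unpaired")
            dims = dim0[ci] + (days - entry[c])
            mu = wood(dims.astype(float), alpha[ci], beta[ci], gamma[ci])
            broken = labels == "broken"
            sd = np.where(broken, config.sd_broken, config.sd_affinity)
            shift = np.where(broken, config.mean_shift_broken, 0.0)
            y = np.maximum(mu + shift + rng.normal(0.0, 1.0, len(days)) * sd, 0.0)
            for d, dm, yy, lb in zip(days, dims, np.round(y, 3), labels):
                milk_rows.append((d, c, pen, float(yy), int(lact[ci]), int(dm), lb))
                label_rows.append((c, pen, d, lb))

        # gate events ----------------------------------------------------
        handled = set()
        for a, b in sorted(pairs):
            handled.update((a, b))
            co_days = np.arange(entry[a], break_day[a] + 1)
            # alternate the trigger role by calendar-day parity
            for trig, foll, par in ((a, b, 0), (b, a, 1)):
                tdays = co_days[co_days % 2 == par]
                t_times = _spontaneous_events(rng, tdays, rate)
                t_times.sort()
                follows = t_times[rng.random(len(t_times)) < config.follow_prob]
                f_times = follows + rng.uniform(1.0, config.follow_gap_seconds, len(follows))
                day_end = (np.floor(follows / SECONDS_PER_DAY) + 1) * SECONDS_PER_DAY - 1
                f_times = np.minimum(f_times, day_end)
                f_own = _spontaneous_events(rng, tdays, rate * (1.0 - config.follow_prob))
                ev_rows["t"].append(t_times)
                ev_rows["cow"].append(np.full(len(t_times), trig, dtype=object))
                ev_rows["pen"].append(np.full(len(t_times), pen, dtype=object))
                for arr, who in ((f_times, foll), (f_own, foll)):
                    ev_rows["t"].append(arr)
                    ev_rows["cow"].append(np.full(len(arr), who, dtype=object))
                    ev_rows["pen"].append(np.full(len(arr), pen, dtype=object))
            # broken tails: the longer-staying mate reverts to independent traffic
            for c in (a, b):
                tail = np.arange(break_day[c] + 1, exit_[c] + 1)
                if len(tail):
                    times = _spontaneous_events(rng, tail, rate)
                    ev_rows["t"].append(times)
                    ev_rows["cow"].append(np.full(len(times), c, dtype=object))
                    ev_rows["pen"].append(np.full(len(times), pen, dtype=object))
        for c in roster:
            if c in handled:
                continue
            days = np.arange(entry[c], exit_[c] + 1)
            times = _spontaneous_events(rng, days, rate)
            ev_rows["t"].append(times)
            ev_rows["cow"].append(np.full(len(times), c, dtype=object))
            ev_rows["pen"].append(np.full(len(times), pen, dtype=object))

    t = np.concatenate(ev_rows["t"]) if ev_rows["t"] else np.empty(0)
    cow = np.concatenate(ev_rows["cow"]) if ev_rows["cow"] else np.empty(0, dtype=object)
    pen_arr = np.concatenate(ev_rows["pen"]) if ev_rows["pen"] else np.empty(0, dtype=object)
    n_ev = len(t)
    dest = np.where(rng.random(n_ev) < config.milking_fraction, "milking", "feeding")
    events = pd.DataFrame(
        {
            "timestamp": start + pd.to_timedelta(np.floor(t).astype(np.int64), unit="s"),
            "cow_id": cow,
            "pen_id": pen_arr,
            "destination": dest,
        }
    ).sort_values(["pen_id", "timestamp"], kind="stable").reset_index(drop=True)

    milk = pd.DataFrame(milk_rows, columns=["day", "cow_id", "pen_id", "yield_kg", "lactation_number", "dim", "label"])
    milk["date"] = start + pd.to_timedelta(milk.pop("day"), unit="D")
    milk = milk[["date", "cow_id", "pen_id", "yield_kg", "lactation_number", "dim", "label"]]

    residency = pd.DataFrame(res_rows, columns=["cow_id", "pen_id", "entry_day", "exit_day"])
    residency["entry_date"] = start + pd.to_timedelta(residency.pop("entry_day"), unit="D")
    residency["exit_date"] = start + pd.to_timedelta(residency.pop("exit_day"), unit="D")
    residency = residency[["cow_id", "pen_id", "entry_date", "exit_date"]].sort_values(
        ["cow_id", "entry_date"], kind="stable"
    ).reset_index(drop=True)

    labels = pd.DataFrame(label_rows, columns=["cow_id", "pen_id", "day", "label"])
    labels["date"] = start + pd.to_timedelta(labels.pop("day"), unit="D")
    labels = labels[["cow_id", "pen_id", "date", "label"]]

    params = pd.DataFrame(
        param_rows, columns=["cow_id", "pen_id", "lactation_number", "alpha", "beta", "gamma", "dim0"]
    )

    truth = GroundTruth(
        planted_pairs=truth_pairs,
        wood_params=params,
        residency=residency,
        labels=labels,
        config=config,
    )
    milk_out = milk.drop(columns="label")
    return HerdData(events, milk_out, residency, truth)


def write_fixture(herd: HerdData, directory) -> dict[str, Path]:
    """Write the herd as the three CSV schemas plus a ground-truth bundle.

    Re-reading the CSVs with the package readers reproduces the in-memory
    tables exactly (yields are rounded to 3 decimals at generation time and
    timestamps carry second resolution).  Identical configs give
    byte-identical files.
    """
    from . import io as hio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gate_events": directory / "gate_events.csv",
        "milk_records": directory / "milk_records.csv",
        "residency": directory / "residency.csv",
        "ground_truth": directory / "ground_truth.json",
        "ground_truth_labels": directory / "ground_truth_labels.csv",
    }
    hio.write_gate_events(herd.gate_events, paths["gate_events"])
    hio.write_milk_records(herd.milk_records, paths["milk_records"])
    hio.write_residency(herd.residency, paths["residency"])

    truth = herd.truth
    bundle = {
        "planted_pairs": {pen: [list(p) for p in pairs] for pen, pairs in truth.planted_pairs.items()},
        "wood_params": truth.wood_params.to_dict(orient="records"),
        "config": _config_dict(truth.config),
    }
    paths["ground_truth"].write_text(json.dumps(bundle, indent=1, sort_keys=True))
    lab = truth.labels.copy()
    lab["date"] = lab["date"].dt.strftime("%Y-%m-%d")
    lab.to_csv(paths["ground_truth_labels"], index=False)
    return paths


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["residency_model"] = asdict(config.residency_model)
    d["wood_param_dists"] = asdict(config.wood_param_dists)
    return d


def simulate_labelled_residuals(
    n_cows: int,
    n_days: int,
    sd_affinity: float,
    sd_broken: float,
    mean_shift_broken: float,
    rng: np.random.Generator,
    pen_id: str = "pen1",
    start_date: str = "2019-02-04",
) -> pd.DataFrame:
    """Labelled daily deviations around the true curve for one pen.

    A lightweight stand-in for the full generator used to study the
    deviation-contrast stage in isolation: each cow gets an affinity period
    followed by a broken period (break day uniform over the middle 40% of
    the window) and daily residuals drawn from the same period-dependent
    noise model the full generator uses.  Columns match the labelled
    residual frame the pipeline produces.
    """
    start = pd.Timestamp(start_date)
    cows = np.array([f"{pen_id}C{i:03d}" for i in range(1, n_cows + 1)], dtype=object)
    brk = rng.integers(int(0.3 * n_days), int(0.7 * n_days), n_cows)
    dim0 = rng.integers(1, 121, n_cows)
    days = np.tile(np.arange(n_days), n_cows)
    cow_col = np.repeat(cows, n_days)
    broken = days >= np.repeat(brk, n_days)
    sd = np.where(broken, sd_broken, sd_affinity)
    shift = np.where(broken, mean_shift_broken, 0.0)
    resid = shift + rng.normal(0.0, 1.0, n_cows * n_days) * sd
    return pd.DataFrame(
        {
            "cow_id": cow_col,
            "pen_id": pen_id,
            "date": start + pd.to_timedelta(days, unit="D"),
            "dim": np.repeat(dim0, n_days) + days,
            "residual_kg": resid,
            "label": np.where(broken, "broken", "affinity"),
        }
    )
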