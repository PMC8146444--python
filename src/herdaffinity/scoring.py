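"""Pairwise affinity scoring of sort-gate passage sequences.

Three schemes turn one pen's timestamped gate log into a symmetric
non-negative score matrix over the pen's cows:

``window15``
    All cows passing the gate within the same fixed 15-minute bin (aligned to
    midnight) share a uniform relationship: each unordered pair of distinct
    cows present in a bin gains one unit per bin, regardless of how many
    times each passed within it.
``inverse_interval``
    Every pair of passages by distinct cows closer than the window length
    contributes ``1 / max(dt_seconds, epsilon_seconds)``.
``lag_sequence``
    Order-based: for each event, the cows at the previous ``max_lag``
    sequence positions receive an exponentially decaying credit
    ``decay_base**-(k-1)`` at lag ``k``; a cow's own events occupy lag slots
    but score nothing.  No time window is involved, so the scheme is immune
    to the overall pace of traffic.

Two normalisations make scores comparable across cows and across the year:
per-event month weights ``w(m) = C_min / C_m`` down-weight months with heavy
gate traffic (up to the ratio of the busiest to the quietest month), and the
final matrix can be divided by ``sqrt(T_a * T_b)`` where ``T_x`` is cow
``x``'s total days of residency in the pen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoringSpec",
    "AffinityNetwork",
    "month_weights",
    "score_lag_sequence",
    "score_window",
    "score_inverse_interval",
    "score_events",
    "normalize_by_residency",
]


@dataclass(frozen=True)
class ScoringSpec:
    """Parameters of an affinity-scoring run.

    Parameters
    ----------
    method : {"lag_sequence", "window15", "inverse_interval"}
    window_minutes : float
        Bin length for ``window15`` and maximum pair separation for
        ``inverse_interval``.
    max_lag : int
        Number of preceding sequence positions credited by ``lag_sequence``.
    decay_base : float
        Base of the exponential lag decay (weights 1, 1/b, 1/b^2, ...).
    epsilon_seconds : float
        Guard for simultaneous passages in ``inverse_interval``.
    apply_month_weights, apply_residency_norm : bool
        Whether the high-level entry points apply the two normalisations.
    """

    method: str = "lag_sequence"
    window_minutes: float = 15.0
    max_lag: int = 4
    decay_base: float = 2.0
    epsilon_seconds: float = 1.0
    apply_month_weights: bool = True
    apply_residency_norm: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("lag_sequence", "window15", "inverse_interval"):
            raise ValueError(f"unknown scoring method {self.method!r}")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.window_minutes <= 0:
            raise ValueError("window_minutes must be > 0")
        if self.decay_base <= 1:
            raise ValueError("decay_base must be > 1")
        if self.epsilon_seconds <= 0:
            raise ValueError("epsilon_seconds must be > 0")


@dataclass
class AffinityNetwork:
    """A pen's symmetric weighted affinity matrix.

    ``weights[i, j]`` is the affinity score between ``cows[i]`` and
    ``cows[j]``; the matrix is symmetric with a zero diagonal and
    non-negative entries.
    """

    pen_id: str
    cows: list[str]
    weights: np.ndarray
    spec: ScoringSpec
    month_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.cows), len(self.cows)):
            raise ValueError("weight matrix shape does not match cow list")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_cows(self) -> int:
        return len(self.cows)

    def score(self, cow_a: str, cow_b: str) -> float:
        i, j = self.cows.index(cow_a), self.cows.index(cow_b)
        return float(self.weights[i, j])

    def to_edge_frame(self) -> pd.DataFrame:
        """Nonzero edges as (pen_id, cow_a, cow_b, score), cow_a < cow_b."""
        iu, ju = np.triu_indices(self.n_cows, k=1)
        mask = self.weights[iu, ju] > 0
        cows = np.asarray(self.cows, dtype=object)
        return pd.DataFrame(
            {
                "pen_id": self.pen_id,
                "cow_a": cows[iu[mask]],
                "cow_b": cows[ju[mask]],
                "score": self.weights[iu[mask], ju[mask]],
            }
        )

    def as_graph(self):
        """Networkx graph with scores as the ``weight`` edge attribute."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.cows)
        edges = self.to_edge_frame()
        g.add_weighted_edges_from(edges[["cow_a", "cow_b", "score"]].itertuples(index=False, name=None))
        return g

    def with_weights(self, weights: np.ndarray) -> "AffinityNetwork":
        return AffinityNetwork(self.pen_id, list(self.cows), weights, self.spec, dict(self.month_weights))


def month_weights(monthly_counts: pd.DataFrame | pd.Series) -> dict[int, float]:
    """Per-month event weights ``w(m) = C_min / C_m`` for one pen.

    Months are calendar months of the year (1-12, pooled across years).
    ``C_min`` is the smallest *nonzero* monthly passage count; months with no
    events get weight 0.  The busiest month is thus down-weighted by exactly
    the ratio of the busiest to the quietest month's traffic.
    """
    if isinstance(monthly_counts, pd.DataFrame):
        counts = monthly_counts.set_index("month")["count"]
    else:
        counts = monthly_counts
    counts = counts.astype(float)
    nonzero = counts[counts > 0]
    if nonzero.empty:
        raise ValueError("need at least one month with a nonzero count")
    c_min = nonzero.min()
    return {int(m): (c_min / c if c > 0 else 0.0) for m, c in counts.items()}


def _prep(events: pd.DataFrame, mweights: dict[str, float] | None):
    """Sorted-time check + cow codes + per-event month weights."""
    ts = events["timestamp"]
    if not ts.is_monotonic_increasing:
        raise ValueError("events must be sorted by timestamp")
    cows = sorted(events["cow_id"].unique())
    codes = pd.Categorical(events["cow_id"], categories=cows).codes.astype(np.int64)
    if mweights is None:
        mw = np.ones(len(events))
    else:
        months = ts.dt.month
        mw = months.map(lambda m: mweights.get(int(m), 0.0)).to_numpy(dtype=float)
    return cows, codes, mw


def _pen_id(events: pd.DataFrame) -> str:
    pens = events["pen_id"].unique()
    if len(pens) > 1:
        raise ValueError("scoring operates on a single pen's events")
    return str(pens[0]) if len(pens) else ""


def score_lag_sequence(events: pd.DataFrame, spec: ScoringSpec, mweights: dict[str, float] | None = None) -> AffinityNetwork:
    """Exponentially decaying credit over the ordered passage sequence.

    For the event at sequence position ``i`` (cow ``c``) and each lag
    ``k = 1..max_lag``, if the event at position ``i-k`` belongs to a
    different cow ``c'``, the pair (c, c') gains
    ``decay_base**-(k-1) * month_weight(event i's month)``.  Lags index
    positions, not distinct cows, so a cow's own intervening events consume
    lag slots silently.  The sequence crosses day boundaries and arbitrary
    time gaps: only order matters.
    """
    cows, codes, mw = _prep(events, mweights)
    n = len(cows)
    acc = np.zeros((n, n))
    for k in range(1, spec.max_lag + 1):
        if k >= len(codes):
            break
        cur, prev = codes[k:], codes[:-k]
        mask = cur != prev
        w = (spec.decay_base ** -(k - 1)) * mw[k:][mask]
        np.add.at(acc, (cur[mask], prev[mask]), w)
    weights = acc + acc.T
    return AffinityNetwork(_pen_id(events), cows, weights, spec, mweights or {})


def score_window(events: pd.DataFrame, spec: ScoringSpec, mweights: dict[str, float] | None = None) -> AffinityNetwork:
    """Uniform relationship within fixed time bins.

    Time is partitioned into consecutive ``window_minutes`` bins aligned to
    midnight; every unordered pair of distinct cows each present at least
    once in a bin gains one unit (times the bin's month weight).  Presence,
    not event count: repeated passes within a bin do not add.
    """
    cows, codes, _ = _prep(events, mweights)
    n = len(cows)
    bin_seconds = int(round(spec.window_minutes * 60))
    secs = events["timestamp"].astype("int64") // 1_000_000_000
    bins = (secs // bin_seconds).to_numpy()

    present = pd.DataFrame({"bin": bins, "code": codes}).drop_duplicates()
    if mweights is None:
        bin_w = pd.Series(1.0, index=pd.unique(present["bin"]))
    else:
        bin_start = pd.to_datetime(pd.unique(present["bin"]) * bin_seconds, unit="s")
        bin_w = pd.Series(
            [mweights.get(int(m), 0.0) for m in bin_start.month],
            index=pd.unique(present["bin"]),
        )
    pairs = present.merge(present, on="bin")
    pairs = pairs[pairs["code_x"] < pairs["code_y"]]
    acc = np.zeros((n, n))
    if len(pairs):
        w = bin_w.reindex(pairs["bin"]).to_numpy()
        np.add.at(acc, (pairs["code_x"].to_numpy(), pairs["code_y"].to_numpy()), w)
    weights = acc + acc.T
    return AffinityNetwork(_pen_id(events), cows, weights, spec, mweights or {})


def score_inverse_interval(events: pd.DataFrame, spec: ScoringSpec, mweights: dict[str, float] | None = None) -> AffinityNetwork:
    """Credit inversely proportional to the inter-passage interval.

    Every pair of events by distinct cows with ``|dt| <= window_minutes``
    contributes ``month_weight / max(dt_seconds, epsilon_seconds)``, the
    month weight being that of the later event.
    """
    cows, codes, mw = _prep(events, mweights)
    n = len(cows)
    t = (events["timestamp"].astype("int64") // 1_000_000_000).to_numpy().astype(np.float64)
    horizon = spec.window_minutes * 60.0
    left = np.searchsorted(t, t - horizon, side="left")
    idx = np.arange(len(t))
    counts = idx - left
    acc = np.zeros((n, n))
    if counts.sum() > 0:
        rows = np.repeat(idx, counts)
        starts = np.repeat(np.cumsum(counts) - counts, counts)
        cols = np.arange(counts.sum()) - starts + np.repeat(left, counts)
        mask = codes[rows] != codes[cols]
        rows, cols = rows[mask], cols[mask]
        dt = np.maximum(t[rows] - t[cols], spec.epsilon_seconds)
        np.add.at(acc, (codes[rows], codes[cols]), mw[rows] / dt)
    weights = acc + acc.T
    return AffinityNetwork(_pen_id(events), cows, weights, spec, mweights or {})


_SCORERS = {
    "lag_sequence": score_lag_sequence,
    "window15": score_window,
    "inverse_interval": score_inverse_interval,
}


def score_events(
    events: pd.DataFrame,
    spec: ScoringSpec | None = None,
    residency: pd.DataFrame | None = None,
    monthly_counts: pd.DataFrame | None = None,
) -> AffinityNetwork:
    """Score one pen's events with the spec's method and normalisations.

    Month weights are derived from ``monthly_counts`` (or computed from the
    events themselves) when ``spec.apply_month_weights``; residency
    normalisation requires a residency table.
    """
    spec = spec or ScoringSpec()
    mweights = None
    if spec.apply_month_weights:
        if monthly_counts is None:
            from .io import monthly_gate_counts

            monthly_counts = monthly_gate_counts(events)
        pen = _pen_id(events)
        counts = monthly_counts[monthly_counts["pen_id"] == pen] if "pen_id" in monthly_counts else monthly_counts
        mweights = month_weights(counts[["month", "count"]])
    net = _SCORERS[spec.method](events, spec, mweights)
    if spec.apply_residency_norm:
        if residency is None:
            raise ValueError("residency table required for residency normalisation")
        net = normalize_by_residency(net, residency)
    return net


def normalize_by_residency(network: AffinityNetwork, residency: pd.DataFrame, mode: str = "geometric") -> AffinityNetwork:
    """Normalise scores by the cows' time in the pen.

    ``mode="geometric"`` (default) divides each pair score by
    ``sqrt(T_a * T_b)`` with ``T_x`` the cow's total days resident in this
    pen — symmetric by construction.  ``mode="overlap"`` divides by the
    number of days both cows were co-resident in the pen.
    """
    res = residency[residency["pen_id"] == network.pen_id]
    days = (res["exit_date"] - res["entry_date"]).dt.days + 1
    totals = days.groupby(res["cow_id"]).sum()
    t = np.array([float(totals.get(c, 0.0)) for c in network.cows])
    if (t <= 0).any():
        missing = [c for c, d in zip(network.cows, t) if d <= 0]
        raise ValueError(f"cows with no residency in pen {network.pen_id}: {missing[:5]}")
    if mode == "geometric":
        denom = np.sqrt(np.outer(t, t))
    elif mode == "overlap":
        denom = _overlap_days(network.cows, res)
        scored = network.weights > 0
        if ((denom == 0) & scored).any():
            raise ValueError("scored pair with zero co-residency overlap")
        denom = np.where(denom == 0, 1.0, denom)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return network.with_weights(network.weights / denom)


def _overlap_days(cows: list[str], res: pd.DataFrame) -> np.ndarray:
    n = len(cows)
    out = np.zeros((n, n))
    by_cow = {c: g for c, g in res.groupby("cow_id")}
    for i, a in enumerate(cows):
        for j in range(i + 1, n):
            b = cows[j]
            total = 0
            for _, ra in by_cow.get(a, pd.DataFrame()).iterrows():
                for _, rb in by_cow.get(b, pd.DataFrame()).iterrows():
                    lo = max(ra["entry_date"], rb["entry_date"])
                    hi = min(ra["exit_date"], rb["exit_date"])
                    total += max(0, (hi - lo).days + 1)
            out[i, j] = out[j, i] = total
    return out


def score_all_pens(
    events: pd.DataFrame,
    spec: ScoringSpec | None = None,
    residency: pd.DataFrame | None = None,
) -> dict[str, AffinityNetwork]:
    """Score every pen in a multi-pen event table."""
    from .io import monthly_gate_counts

    spec = spec or ScoringSpec()
    counts = monthly_gate_counts(events)
    return {
        str(pen): score_events(g.reset_index(drop=True), spec, residency, counts)
        for pen, g in events.groupby("pen_id", sort=True)
    }
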