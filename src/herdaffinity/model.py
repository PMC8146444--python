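"""The top-level herd-affinity model: data in, fitted analysis out.

``HerdAffinityModel`` bundles the three input tables and the analysis
options; ``fit()`` runs the whole chain — residency filter, per-pen affinity
scoring, exclusive pair matching, Wood lactation baselines, period
labelling and the per-pen paired deviation tests — and returns a
``HerdAffinityResults`` that carries every intermediate product and renders
a summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as hio
from .effect import dim_balance_check, effect_report, label_periods, pen_paired_test, summarize_deviation
from .lactation import WoodLactationModel
from .matching import MatchedPair, pairs_frame, stepwise_match
from .network import compute_metrics, edge_percentile_subgraph, metrics_frame
from .scoring import ScoringSpec, score_all_pens

__all__ = ["HerdAffinityModel", "HerdAffinityResults"]


class HerdAffinityModel:
    """Affinity-pair analysis of one herd's gate, milk and residency data.

    Parameters
    ----------
    gate_events, milk_records : DataFrame
        Tables in the package's gate-event / milk-record schemas.
    residency : DataFrame, optional
        Explicit residency intervals; inferred from the gate events
        (majority-pen rule, gaps of up to 3 silent days bridged) if omitted.
    scoring : ScoringSpec
        Affinity scoring method and normalisation flags (default: lag
        sequence with month weights and residency normalisation).
    matching_mode : {"exclusive", "non_exclusive"}
        Exclusive = stable roommates with blossom fallback.
    min_residency_days : int
        Cows below this total residency are dropped everywhere.
    min_obs, min_period_days, alternative : fitting/testing options.
    """

    def __init__(
        self,
        gate_events: pd.DataFrame,
        milk_records: pd.DataFrame,
        residency: pd.DataFrame | None = None,
        scoring: ScoringSpec | None = None,
        matching_mode: str = "exclusive",
        min_residency_days: int = 30,
        min_obs: int = 5,
        min_period_days: int = 7,
        alternative: str = "greater",
    ):
        if residency is None:
            residency = hio.infer_residency(gate_events)
        self.gate_events, self.milk_records, self.residency, self.excluded_cows = hio.filter_herd(
            gate_events, milk_records, residency, min_residency_days
        )
        self.scoring = scoring or ScoringSpec()
        self.matching_mode = matching_mode
        self.min_residency_days = min_residency_days
        self.min_obs = min_obs
        self.min_period_days = min_period_days
        self.alternative = alternative

    @classmethod
    def from_csv(cls, gate_path, milk_path, residency_path=None, **kwargs) -> "HerdAffinityModel":
        events = hio.read_gate_events(gate_path)
        milk = hio.read_milk_records(milk_path)
        residency = hio.read_residency(residency_path) if residency_path else None
        return cls(events, milk, residency, **kwargs)

    def fit(self) -> "HerdAffinityResults":
        networks = score_all_pens(self.gate_events, self.scoring, self.residency)
        pairs: list[MatchedPair] = []
        for pen in sorted(networks):
            pairs.extend(stepwise_match(networks[pen], self.matching_mode))
        pair_df = pairs_frame(pairs)

        lact_results = WoodLactationModel(self.milk_records, self.min_obs).fit()
        resid = lact_results.residuals()

        periods = label_periods(pair_df, self.residency)
        labelled = resid.merge(periods[["cow_id", "date", "label"]], on=["cow_id", "date"], how="inner")
        pen_tests = pen_paired_test(labelled, self.min_period_days, self.alternative)
        summaries = summarize_deviation(resid, periods, self.min_period_days)
        try:
            balance = dim_balance_check(labelled)
        except ValueError:
            balance = None
        return HerdAffinityResults(
            model=self,
            networks=networks,
            pairs=pairs,
            pair_df=pair_df,
            lactation=lact_results,
            residual_frame=resid,
            periods=periods,
            labelled_residuals=labelled,
            summaries=summaries,
            pen_tests=pen_tests,
            dim_balance=balance,
        )


class HerdAffinityResults:
    """Everything the fitted analysis produced.

    Attributes
    ----------
    networks : dict pen -> AffinityNetwork
    pairs : list of MatchedPair (pair_df as a DataFrame)
    lactation : WoodLactationResults
    periods, labelled_residuals, summaries : intermediate frames
    pen_tests : per-pen paired-test table with Holm-adjusted p-values
    dim_balance : DIM confounding diagnostic (or None)
    """

    def __init__(self, model, networks, pairs, pair_df, lactation, residual_frame,
                 periods, labelled_residuals, summaries, pen_tests, dim_balance):
        self.model = model
        self.networks = networks
        self.pairs = pairs
        self.pair_df = pair_df
        self.lactation = lactation
        self.residual_frame = residual_frame
        self.periods = periods
        self.labelled_residuals = labelled_residuals
        self.summaries = summaries
        self.pen_tests = pen_tests
        self.dim_balance = dim_balance

    def network_metrics(self, distance: str = "weight") -> pd.DataFrame:
        return metrics_frame({p: compute_metrics(n, distance) for p, n in self.networks.items() if n.n_cows >= 2})

    def summary(self) -> str:
        lines = ["Herd affinity analysis", "=" * 64]
        lines.append(f"pens: {len(self.networks)}   matched pairs: {len(self.pairs)}   "
                     f"cows excluded by residency filter: {len(self.model.excluded_cows)}")
        metrics = self.network_metrics()
        if len(metrics):
            lines.append("")
            lines.append("Network metrics (edge weights as path lengths)")
            lines.append(metrics.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(self.lactation.summary())
        lines.append("")
        lines.append(effect_report(self.pen_tests))
        if self.dim_balance is not None:
            lines.append("")
            lines.append(
                f"DIM balance: KS statistic {self.dim_balance['ks_statistic']:.3f} over "
                f"{self.dim_balance['n_affinity_days']} affinity and "
                f"{self.dim_balance['n_broken_days']} broken cow-days"
            )
        return "\n".join(lines)

    def to_csv(self, directory) -> dict:
        """Persist every artifact as deterministic CSVs; returns the paths."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(name, df, date_cols=()):
            df = df.copy()
            for c in date_cols:
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
            p = directory / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p

        scores = pd.concat([n.to_edge_frame() for n in self.networks.values()], ignore_index=True)
        _write("scores", scores)
        _write("metrics", self.network_metrics())
        _write("pairs", self.pair_df)
        _write("fits", self.lactation.params)
        resid = self.residual_frame
        cols = [c for c in ["cow_id", "pen_id", "lactation_number", "date", "dim", "observed_kg", "expected_kg", "residual_kg"] if c in resid.columns]
        _write("residuals", resid[cols], date_cols=("date",))
        _write("summaries", self.summaries)
        _write("effects", self.pen_tests)
        (directory / "report.txt").write_text(self.summary() + "\n")
        paths["report"] = directory / "report.txt"
        return paths

    def plot_network(self, pen_id: str, top_fraction: float = 0.10, ax=None):
        """Circular plot of a pen's strongest edges (declutters dense pens)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        net = edge_percentile_subgraph(self.networks[pen_id], top_fraction)
        g = net.as_graph()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        pos = nx.circular_layout(sorted(g.nodes))
        weights = np.array([d["weight"] for _, _, d in g.edges(data=True)])
        alphas = 0.2 + 0.8 * (weights / weights.max()) if len(weights) else []
        nx.draw_networkx_nodes(g, pos, ax=ax, node_size=40, node_color="#777777")
        nx.draw_networkx_edges(g, pos, ax=ax, alpha=alphas, edge_color="tab:blue")
        nx.draw_networkx_labels(g, pos, ax=ax, font_size=6)
        ax.set_title(f"{pen_id}: top {top_fraction:.0%} of edge weights")
        ax.set_axis_off()
        return ax

    def plot_effect(self, ax=None):
        """Per-pen mean deviation during affinity vs broken periods."""
        import matplotlib.pyplot as plt

        t = self.pen_tests[self.pen_tests["pen_id"] != "Overall"]
        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(t))
        ax.bar(x - 0.2, t["mean_affinity"], width=0.4, label="affinity", color="tab:green")
        ax.bar(x + 0.2, t["mean_broken"], width=0.4, label="broken", color="tab:red")
        ax.set_xticks(x, t["pen_id"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("mean deviation from Wood curve (kg/day)")
        ax.legend()
        return ax
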