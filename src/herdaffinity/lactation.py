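"""Wood lactation curves as per-cow expected-production baselines.

The Wood curve

    Y(t) = alpha * t**beta * exp(-gamma * t)

is the classical gamma-shaped lactation curve: yield rises from calving to a
peak at ``t = beta / gamma`` days in milk (DIM) and then decays.  One curve
is fitted per cow x lactation by bounded nonlinear least squares; the fitted
curve is each cow's "synthetic" expected daily yield, and the observed minus
expected residuals are the material for the affinity-period contrast.

Fitting: the log-linearisation ``ln Y = ln alpha + beta ln t - gamma t`` is
solved by ordinary least squares for the starting point, then the raw
(non-log) residual sum of squares is minimised by a trust-region reflective
solver within the bounds alpha in (0, 200], beta in (0, 3], gamma in
[0, 0.5].  The trust-region step never increases the objective, so the final
RSS is at most the starting RSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "wood",
    "LactationFit",
    "fit_lactation",
    "residuals",
    "WoodLactationModel",
    "WoodLactationResults",
]

BOUNDS_LO = np.array([1e-6, 1e-6, 0.0])
BOUNDS_HI = np.array([200.0, 3.0, 0.5])


def wood(t, alpha: float, beta: float, gamma: float):
    """Wood-curve expected yield (kg) at DIM ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    out = alpha * np.power(t, beta) * np.exp(-gamma * t)
    return out if out.ndim else float(out)


@dataclass
class LactationFit:
    """Fitted Wood parameters for one cow x lactation."""

    cow_id: str
    lactation_number: int
    alpha: float
    beta: float
    gamma: float
    n_obs: int
    rss: float
    converged: bool

    def predict(self, t):
        return wood(t, self.alpha, self.beta, self.gamma)

    @property
    def peak_dim(self) -> float:
        """DIM of peak yield, beta/gamma (inf for a non-decaying curve)."""
        return self.beta / self.gamma if self.gamma > 0 else float("inf")


def _loglinear_start(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS on ln Y = ln a + b ln t - g t, clipped inside the bounds."""
    x = np.column_stack([np.ones_like(t), np.log(t), -t])
    coef, *_ = np.linalg.lstsq(x, np.log(y), rcond=None)
    start = np.array([np.exp(coef[0]), coef[1], coef[2]])
    lo = BOUNDS_LO + np.array([1e-8, 1e-8, 0.0])
    hi = BOUNDS_HI - 1e-8
    return np.clip(start, lo, hi)


def fit_lactation(records: pd.DataFrame, min_obs: int = 5) -> LactationFit | None:
    """Fit one Wood curve to one cow x lactation's daily records.

    ``records`` needs columns cow_id, lactation_number, dim, yield_kg.
    Records with DIM < 1 or non-positive yield are unusable for the
    log-linear start and are dropped; groups with fewer than ``min_obs``
    usable records are skipped (``None`` returned).
    """
    usable = records[(records["dim"] >= 1) & (records["yield_kg"] > 0)]
    if len(usable) < min_obs:
        return None
    t = usable["dim"].to_numpy(dtype=float)
    y = usable["yield_kg"].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]

    x0 = _loglinear_start(t, y)

    def resid(p):
        return wood(t, *p) - y

    sol = least_squares(resid, x0, bounds=(BOUNDS_LO, BOUNDS_HI), method="trf", xtol=1e-12, ftol=1e-12)
    rss = float(np.sum(sol.fun**2))
    return LactationFit(
        cow_id=str(records["cow_id"].iloc[0]),
        lactation_number=int(records["lactation_number"].iloc[0]),
        alpha=float(sol.x[0]),
        beta=float(sol.x[1]),
        gamma=float(sol.x[2]),
        n_obs=len(usable),
        rss=rss,
        converged=bool(sol.success),
    )


def residuals(records: pd.DataFrame, fit: LactationFit) -> pd.DataFrame:
    """Observed minus expected yield per recorded day.

    Only days with a record appear (missing days are absent, not zero).
    """
    out = records.loc[records["dim"] >= 1, ["cow_id", "date", "dim", "yield_kg"]].copy()
    out["expected_kg"] = fit.predict(out["dim"].to_numpy(dtype=float))
    out["residual_kg"] = out["yield_kg"] - out["expected_kg"]
    return out.rename(columns={"yield_kg": "observed_kg"}).reset_index(drop=True)


class WoodLactationModel:
    """Per-cow-x-lactation Wood-curve model over a milk-record table.

    Parameters
    ----------
    milk : DataFrame
        Daily milk records (cow_id, date, yield_kg, lactation_number, dim).
    min_obs : int
        Minimum usable records per cow x lactation; smaller groups are
        flagged and skipped rather than fitted.
    """

    def __init__(self, milk: pd.DataFrame, min_obs: int = 5):
        self.milk = milk
        self.min_obs = int(min_obs)

    def fit(self) -> "WoodLactationResults":
        fits: dict[tuple[str, int], LactationFit] = {}
        skipped: list[tuple[str, int]] = []
        for (cow, lact), g in self.milk.groupby(["cow_id", "lactation_number"], sort=True):
            f = fit_lactation(g, self.min_obs)
            if f is None:
                skipped.append((str(cow), int(lact)))
            else:
                fits[(str(cow), int(lact))] = f
        return WoodLactationResults(self, fits, skipped)


class WoodLactationResults:
    """Fitted curves, their parameters and per-day residuals."""

    def __init__(self, model: WoodLactationModel, fits, skipped):
        self.model = model
        self.fits = fits
        self.skipped = skipped

    @property
    def params(self) -> pd.DataFrame:
        rows = [
            {
                "cow_id": f.cow_id,
                "lactation_number": f.lactation_number,
                "alpha": f.alpha,
                "beta": f.beta,
                "gamma": f.gamma,
                "n_obs": f.n_obs,
                "rss": f.rss,
                "converged": f.converged,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows, columns=["cow_id", "lactation_number", "alpha", "beta", "gamma", "n_obs", "rss", "converged"])

    def predict(self, cow_id: str, lactation_number: int, t):
        return self.fits[(cow_id, int(lactation_number))].predict(t)

    def residuals(self) -> pd.DataFrame:
        """Observed-minus-expected deviations for every converged fit.

        Unconverged groups (typically very short, ill-conditioned
        lactation windows) provide no trustworthy baseline and are omitted.
        """
        frames = []
        for (cow, lact), g in self.model.milk.groupby(["cow_id", "lactation_number"], sort=True):
            f = self.fits.get((str(cow), int(lact)))
            if f is None or not f.converged:
                continue
            r = residuals(g, f)
            r["lactation_number"] = int(lact)
            if "pen_id" in g.columns:
                r["pen_id"] = g["pen_id"].iloc[0]
            frames.append(r)
        if not frames:
            return pd.DataFrame(columns=["cow_id", "date", "dim", "observed_kg", "expected_kg", "residual_kg"])
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Wood lactation curve fits",
            f"  groups fitted : {len(p)}",
            f"  groups skipped: {len(self.skipped)} (fewer than {self.model.min_obs} usable records)",
        ]
        if len(p):
            lines += [
                f"  alpha  mean {p['alpha'].mean():8.3f}  sd {p['alpha'].std(ddof=0):7.3f}",
                f"  beta   mean {p['beta'].mean():8.4f}  sd {p['beta'].std(ddof=0):7.4f}",
                f"  gamma  mean {p['gamma'].mean():8.5f}  sd {p['gamma'].std(ddof=0):7.5f}",
                f"  median RSS/obs {float((p['rss'] / p['n_obs']).median()):.3f} kg^2",
            ]
        return "\n".join(lines)

    def plot_curve(self, cow_id: str, lactation_number: int, ax=None):
        """Observed daily yields and the fitted curve for one cow."""
        import matplotlib.pyplot as plt

        f = self.fits[(cow_id, int(lactation_number))]
        g = self.model.milk
        g = g[(g["cow_id"] == cow_id) & (g["lactation_number"] == lactation_number)]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(g["dim"], g["yield_kg"], s=8, alpha=0.5, label="observed")
        grid = np.arange(1, max(306, int(g["dim"].max()) + 1))
        ax.plot(grid, f.predict(grid), color="C1", label="Wood fit")
        ax.set_xlabel("days in milk")
        ax.set_ylabel("daily yield (kg)")
        ax.set_title(f"{cow_id} L{lactation_number}")
        ax.legend()
        return ax
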