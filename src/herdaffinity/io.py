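"""Reading, validation and residency handling for herd data tables.

Three CSV schemas (UTF-8, header required, RFC-4180 quoting):

* ``gate_events.csv``  — timestamp, cow_id, pen_id, destination
* ``milk_records.csv`` — date, cow_id, pen_id, yield_kg, lactation_number, dim
* ``residency.csv``    — cow_id, pen_id, entry_date, exit_date  (inclusive)

Readers never raise on malformed *rows*: bad rows are dropped, counted and
logged, and a report dict is attached to the returned frame under
``df.attrs["io_report"]`` so that rows read == rows kept + rows rejected.
Missing *columns* are a hard error.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GATE_COLUMNS = ["timestamp", "cow_id", "pen_id", "destination"]
MILK_COLUMNS = ["date", "cow_id", "pen_id", "yield_kg", "lactation_number", "dim"]
RESIDENCY_COLUMNS = ["cow_id", "pen_id", "entry_date", "exit_date"]
DESTINATIONS = ("milking", "feeding", "unknown")


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _attach_report(df: pd.DataFrame, n_read: int, n_rejected: int, reasons: dict) -> pd.DataFrame:
    df.attrs["io_report"] = {
        "n_read": int(n_read),
        "n_kept": int(len(df)),
        "n_rejected": int(n_rejected),
        "reasons": {k: int(v) for k, v in reasons.items() if v},
    }
    if n_rejected:
        logger.warning("rejected %d of %d rows (%s)", n_rejected, n_read, df.attrs["io_report"]["reasons"])
    return df


def read_gate_events(path) -> pd.DataFrame:
    """Read a gate-event CSV, sorted by timestamp within pen.

    Sorting is stable, so events with identical timestamps keep their input
    order.  Rows with unparseable timestamps or empty ids are rejected and
    counted; unexpected destination labels are coerced to ``"unknown"``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, GATE_COLUMNS, path)
    n_read = len(raw)
    reasons: dict[str, int] = {}

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad_ts = ts.isna()
    bad_id = (raw["cow_id"].str.strip() == "") | (raw["pen_id"].str.strip() == "")
    bad = bad_ts | bad_id
    reasons["unparseable_timestamp"] = int(bad_ts.sum())
    reasons["empty_id"] = int((bad_id & ~bad_ts).sum())

    df = pd.DataFrame(
        {
            "timestamp": ts[~bad],
            "cow_id": raw.loc[~bad, "cow_id"],
            "pen_id": raw.loc[~bad, "pen_id"],
            "destination": raw.loc[~bad, "destination"],
        }
    )
    coerced = ~df["destination"].isin(DESTINATIONS)
    if coerced.any():
        reasons["destination_coerced_to_unknown"] = int(coerced.sum())
        df.loc[coerced, "destination"] = "unknown"
    df = df.sort_values(["pen_id", "timestamp"], kind="stable").reset_index(drop=True)
    return _attach_report(df, n_read, int(bad.sum()), reasons)


def read_milk_records(path) -> pd.DataFrame:
    """Read a daily milk-record CSV.

    Duplicate (cow, date) rows are collapsed by summing their yields with a
    warning (per-session records folded into a daily total); rows with
    negative yield, unparseable fields, dim < 1 or lactation < 1 are rejected.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, MILK_COLUMNS, path)
    n_read = len(raw)
    reasons: dict[str, int] = {}

    date = pd.to_datetime(raw["date"], errors="coerce", format="ISO8601")
    yield_kg = pd.to_numeric(raw["yield_kg"], errors="coerce")
    lact = pd.to_numeric(raw["lactation_number"], errors="coerce")
    dim = pd.to_numeric(raw["dim"], errors="coerce")

    bad_parse = date.isna() | yield_kg.isna() | lact.isna() | dim.isna()
    bad_value = (~bad_parse) & ((yield_kg < 0) | (lact < 1) | (dim < 1))
    bad_id = (raw["cow_id"].str.strip() == "") | (raw["pen_id"].str.strip() == "")
    bad = bad_parse | bad_value | bad_id
    reasons["unparseable_field"] = int(bad_parse.sum())
    reasons["invalid_value"] = int(bad_value.sum())
    reasons["empty_id"] = int((bad_id & ~bad_parse & ~bad_value).sum())

    df = pd.DataFrame(
        {
            "date": date[~bad].dt.normalize(),
            "cow_id": raw.loc[~bad, "cow_id"],
            "pen_id": raw.loc[~bad, "pen_id"],
            "yield_kg": yield_kg[~bad].astype(float),
            "lactation_number": lact[~bad].astype(int),
            "dim": dim[~bad].astype(int),
        }
    )

    dup = df.duplicated(subset=["cow_id", "date"], keep=False)
    if dup.any():
        logger.warning("summing yields over %d duplicate (cow, date) rows", int(dup.sum()))
        reasons["duplicate_rows_summed"] = int(dup.sum())
        df = (
            df.groupby(["cow_id", "date"], as_index=False)
            .agg(
                pen_id=("pen_id", "first"),
                yield_kg=("yield_kg", "sum"),
                lactation_number=("lactation_number", "first"),
                dim=("dim", "first"),
            )
        )
    df = df.sort_values(["cow_id", "date"], kind="stable").reset_index(drop=True)
    df = df[MILK_COLUMNS]
    return _attach_report(df, n_read, int(bad.sum()), reasons)


def read_residency(path) -> pd.DataFrame:
    """Read an explicit residency CSV (entry/exit dates inclusive)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, RESIDENCY_COLUMNS, path)
    n_read = len(raw)
    entry = pd.to_datetime(raw["entry_date"], errors="coerce", format="ISO8601")
    exit_ = pd.to_datetime(raw["exit_date"], errors="coerce", format="ISO8601")
    bad = entry.isna() | exit_.isna() | (entry > exit_) | (raw["cow_id"].str.strip() == "")
    df = pd.DataFrame(
        {
            "cow_id": raw.loc[~bad, "cow_id"],
            "pen_id": raw.loc[~bad, "pen_id"],
            "entry_date": entry[~bad].dt.normalize(),
            "exit_date": exit_[~bad].dt.normalize(),
        }
    ).sort_values(["cow_id", "entry_date"], kind="stable").reset_index(drop=True)
    return _attach_report(df, n_read, int(bad.sum()), {"invalid_row": int(bad.sum())})


def infer_residency(events: pd.DataFrame, max_silent_days: int = 3) -> pd.DataFrame:
    """Derive residency intervals from the gate-event stream.

    Each cow-day with at least one event is assigned the pen holding the
    majority of that day's events (ties go to the pen of the day's first
    event).  Residency intervals are maximal runs of same-pen days, bridging
    event-free gaps of at most ``max_silent_days`` days; a pen change always
    splits an interval.
    """
    if events.empty:
        return pd.DataFrame(columns=RESIDENCY_COLUMNS)
    ev = events.copy()
    ev["date"] = ev["timestamp"].dt.normalize()

    # majority pen per cow-day, ties -> pen of the day's first event
    def _day_pen(g: pd.DataFrame) -> str:
        counts = g["pen_id"].value_counts()
        top = counts[counts == counts.max()].index
        if len(top) == 1:
            return top[0]
        return g.sort_values("timestamp", kind="stable")["pen_id"].iloc[0]

    day_pen = (
        ev.sort_values("timestamp", kind="stable")
        .groupby(["cow_id", "date"], sort=True)
        .apply(_day_pen, include_groups=False)
        .rename("pen_id")
        .reset_index()
    )

    rows = []
    for cow, g in day_pen.groupby("cow_id", sort=True):
        g = g.sort_values("date")
        start = prev_date = g["date"].iloc[0]
        prev_pen = g["pen_id"].iloc[0]
        for date, pen in zip(g["date"].iloc[1:], g["pen_id"].iloc[1:]):
            gap = (date - prev_date).days - 1
            if pen != prev_pen or gap > max_silent_days:
                rows.append((cow, prev_pen, start, prev_date))
                start = date
            prev_date, prev_pen = date, pen
        rows.append((cow, prev_pen, start, prev_date))
    return pd.DataFrame(rows, columns=RESIDENCY_COLUMNS)


def residency_days(residency: pd.DataFrame) -> pd.Series:
    """Total resident days per cow (inclusive intervals, summed over pens)."""
    if residency.empty:
        return pd.Series(dtype=int, name="days")
    days = (residency["exit_date"] - residency["entry_date"]).dt.days + 1
    return days.groupby(residency["cow_id"]).sum().rename("days")


def apply_residency_filter(residency: pd.DataFrame, min_days: int = 30) -> tuple[pd.DataFrame, list[str]]:
    """Drop cows whose total residency is below ``min_days``.

    The threshold is exclusive: a cow with exactly ``min_days`` total days is
    retained.  Returns the filtered residency table and the excluded cow ids.
    """
    totals = residency_days(residency)
    excluded = sorted(totals.index[totals < min_days])
    kept = residency[~residency["cow_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def filter_herd(
    events: pd.DataFrame,
    milk: pd.DataFrame,
    residency: pd.DataFrame,
    min_days: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Apply the short-residency filter to every table at once."""
    kept_res, excluded = apply_residency_filter(residency, min_days)
    bad = set(excluded)
    ev = events[~events["cow_id"].isin(bad)].reset_index(drop=True)
    mk = milk[~milk["cow_id"].isin(bad)].reset_index(drop=True)
    if excluded:
        logger.info("residency filter removed %d cows (< %d total days)", len(excluded), min_days)
    return ev, mk, kept_res, excluded


def monthly_gate_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Gate-passage counts per pen per calendar month (1-12).

    Months are calendar months of the year, pooled across years, so a study
    window that starts and ends mid-month (e.g. February to February) still
    sees each month with full coverage.  All 12 months are reported for
    every pen, with zero for months without events, so per-pen counts always
    sum to the total.
    """
    if events.empty:
        return pd.DataFrame(columns=["pen_id", "month", "count"])
    month = events["timestamp"].dt.month
    counts = (
        pd.DataFrame({"pen_id": events["pen_id"], "month": month})
        .groupby(["pen_id", "month"])
        .size()
        .rename("count")
    )
    pens = sorted(events["pen_id"].unique())
    full = pd.MultiIndex.from_product([pens, range(1, 13)], names=["pen_id", "month"])
    return counts.reindex(full, fill_value=0).reset_index()


def validate_milk_consistency(milk: pd.DataFrame) -> pd.DataFrame:
    """Flag DIM/lactation bookkeeping glitches without altering the data.

    Reports rows where, within a cow and lactation, DIM does not advance by
    exactly the calendar-day step, or where lactation number decreases over
    time — the kind of miscoded records a herd-management export can contain.
    """
    flags = []
    for cow, g in milk.sort_values("date").groupby("cow_id", sort=True):
        d_days = g["date"].diff().dt.days
        d_dim = g["dim"].diff()
        same_lact = g["lactation_number"].diff() == 0
        bad_dim = same_lact & d_days.notna() & (d_dim != d_days)
        bad_lact = g["lactation_number"].diff() < 0
        for idx in g.index[bad_dim | bad_lact]:
            flags.append((cow, g.loc[idx, "date"], "dim_step" if bad_dim.get(idx, False) else "lactation_decrease"))
    return pd.DataFrame(flags, columns=["cow_id", "date", "issue"])


def write_gate_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_milk_records(milk: pd.DataFrame, path) -> None:
    out = milk.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out["yield_kg"] = np.round(out["yield_kg"].astype(float), 3)
    out.to_csv(path, index=False, float_format="%.3f")


def write_residency(residency: pd.DataFrame, path) -> None:
    out = residency.copy()
    for col in ("entry_date", "exit_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
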