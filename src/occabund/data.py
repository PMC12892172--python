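"""Domain tables, raw-record readers, and temporal collation.

The analysis unit is the *plot-period*: a 1-ha plot in either one calendar
month of the active season (April-July; the "short" timescale) or the whole
April-July season of a year (the "long" timescale).  Raw encounter and
track-tube check records are collated into per-plot-period sufficient
statistics:

* ``CaptureSummary`` rows -- unique individuals captured ``M``, total
  captures ``n``, capture occasions ``t`` (Huggins sufficient statistics);
* ``OccupancySummary`` rows -- subplots surveyed ``s``, subplots with at
  least one detection ``s_star``, total detections ``d``, checks per subplot
  ``k``, plus the binary plot-selection covariate ``X``.

Collation rules:

* a live-trapping session belongs to the calendar month it occurred in; at
  the long timescale an *occasion* is a whole session (an individual scores
  1 if captured at least once within it);
* a tube check belongs to the calendar month containing the midpoint of its
  check interval (a midpoint at exact midnight on a month boundary is
  assigned to the earlier month); at the long timescale all April-July
  checks of a year are pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

SHORT = "short"
LONG = "long"
ACTIVE_MONTHS = (4, 5, 6, 7)

CAPTURE_SUMMARY_COLS = ["plot_id", "year", "month", "M", "n", "t"]
OCCUPANCY_SUMMARY_COLS = ["plot_id", "year", "month", "s", "s_star", "d", "k"]

_RAW_CAPTURE_COLS = {"individual_id", "plot_id", "year", "month", "session_id",
                     "occasion_index", "captured"}
_RAW_TUBE_COLS = {"subplot_id", "plot_id", "year", "check_start_date",
                  "check_end_date", "detected"}


@dataclass(frozen=True)
class HomeRangeSpec:
    """Home-range diameter summary used for the effective trapping area.

    ``mean_d``/``sd_d`` are the mean of per-individual maximum inter-trap
    distances and its standard error, in metres; ``L`` is the side length of
    the trapping array in metres (37.5 m for a 50-m grid with 4 evenly
    spaced traps per side).
    """

    mean_d: float
    sd_d: float
    L: float = 37.5

    def __post_init__(self) -> None:
        if self.mean_d <= 0:
            raise ValueError("mean_d must be positive")
        if self.sd_d < 0:
            raise ValueError("sd_d must be non-negative")
        if self.L <= 0:
            raise ValueError("L must be positive")


#: Defaults estimated from individuals trapped at least twice.
SHORT_HOMERANGE = HomeRangeSpec(mean_d=11.52, sd_d=1.04, L=37.5)
LONG_HOMERANGE = HomeRangeSpec(mean_d=20.19, sd_d=1.42, L=37.5)


def default_homerange(timescale: str) -> HomeRangeSpec:
    _check_timescale(timescale)
    return SHORT_HOMERANGE if timescale == SHORT else LONG_HOMERANGE


def _check_timescale(timescale: str) -> None:
    if timescale not in (SHORT, LONG):
        raise ValueError(f"timescale must be {SHORT!r} or {LONG!r}, got {timescale!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_captures_raw(path) -> pd.DataFrame:
    """Read a raw encounter-record CSV.

    Expected columns: individual_id (blank for schedule rows marking trapped
    occasions with no capture), plot_id, year, month, session_id,
    occasion_index, captured in {0,1}, optional x_m, y_m trap coordinates.
    """
    df = pd.read_csv(path, dtype={"plot_id": str, "session_id": str})
    df["individual_id"] = df.get("individual_id", pd.Series(dtype=object)).fillna("").astype(str)
    missing = _RAW_CAPTURE_COLS - set(df.columns)
    if missing:
        raise ValueError(f"captures_raw is missing columns: {sorted(missing)}")
    return df


def read_tubes_raw(path) -> pd.DataFrame:
    """Read a raw track-tube check CSV (ISO-8601 interval dates)."""
    df = pd.read_csv(path, dtype={"plot_id": str, "subplot_id": str},
                     parse_dates=["check_start_date", "check_end_date"])
    missing = _RAW_TUBE_COLS - set(df.columns)
    if missing:
        raise ValueError(f"tubes_raw is missing columns: {sorted(missing)}")
    return df


def read_plots(path) -> pd.DataFrame:
    """Read the plot registry (plot_id, subpopulation, selection_method)."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    need = {"plot_id", "subpopulation", "selection_method"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"plots registry is missing columns: {sorted(missing)}")
    bad = set(df["selection_method"]) - {"random", "nonrandom"}
    if bad:
        raise ValueError(f"unknown selection_method values: {sorted(bad)}")
    if df["plot_id"].duplicated().any():
        raise ValueError("duplicate plot_id in registry")
    df = df.copy()
    df["X"] = (df["selection_method"] == "nonrandom").astype(int)
    return df


# ---------------------------------------------------------------------------
# collation
# ---------------------------------------------------------------------------

def _reject_already_collated(df: pd.DataFrame, cols) -> None:
    if set(cols) <= set(df.columns):
        raise ValueError(
            "input looks already collated (summary columns present); "
            "collation is not re-applied to summaries"
        )


def _drop_inactive_months(df: pd.DataFrame, months: pd.Series, what: str) -> pd.DataFrame:
    ok = months.isin(ACTIVE_MONTHS)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} {what} records outside April-July were dropped",
            stacklevel=3,
        )
    return df.loc[ok.to_numpy()]


def collate_captures(raw: pd.DataFrame, timescale: str = SHORT) -> pd.DataFrame:
    """Collate raw encounter records into per-plot-period Huggins statistics.

    Schedule rows (blank ``individual_id``, ``captured == 0``) declare
    trapped occasions with no captures, so plot-periods with M = 0 retain
    their scheduled occasion count ``t``.  Duplicate
    (individual, session, occasion) rows are collapsed by maximum.
    """
    _check_timescale(timescale)
    _reject_already_collated(raw, ["M", "n", "t"])
    missing = _RAW_CAPTURE_COLS - set(raw.columns)
    if missing:
        raise ValueError(f"raw capture records missing columns: {sorted(missing)}")
    df = raw.copy()
    df["individual_id"] = df["individual_id"].fillna("").astype(str)
    df = _drop_inactive_months(df, df["month"], "capture")
    if df.empty:
        return pd.DataFrame(columns=CAPTURE_SUMMARY_COLS)

    # collapse duplicate (individual, occasion) rows
    df = (
        df.groupby(["plot_id", "year", "month", "session_id", "occasion_index",
                    "individual_id"], as_index=False)["captured"].max()
    )

    if timescale == SHORT:
        group = ["plot_id", "year", "month"]
        occ_cols = ["session_id", "occasion_index"]
        per_ind = df
    else:
        group = ["plot_id", "year"]
        occ_cols = ["session_id"]
        # an individual's occasion outcome is 1 if captured at least once
        # within the 3-night session
        per_ind = (
            df.groupby(["plot_id", "year", "session_id", "individual_id"],
                       as_index=False)["captured"].max()
        )

    out = []
    for key, g in per_ind.groupby(group, sort=True):
        # schedule rows (blank individual) keep every occasion represented
        t = g[occ_cols].drop_duplicates().shape[0]
        caught = g[g["individual_id"] != ""]
        n = int(caught["captured"].sum())
        M = int(caught.loc[caught["captured"] > 0, "individual_id"].nunique())
        row = dict(zip(group, key if isinstance(key, tuple) else (key,)))
        row.setdefault("month", pd.NA)
        out.append({**row, "M": M, "n": n, "t": t})
    res = pd.DataFrame(out, columns=CAPTURE_SUMMARY_COLS)
    res["month"] = res["month"].astype("Int64")
    res = res[res["t"] >= 1].reset_index(drop=True)
    validate_capture_summary(res, timescale)
    return res


def _midpoint_month(start: pd.Series, end: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Calendar month/year of the midpoint; midnight month-boundary ties go
    to the earlier month."""
    mid = start + (end - start) / 2
    on_boundary = (mid.dt.day == 1) & (mid.dt.normalize() == mid)
    mid = mid.where(~on_boundary, mid - pd.Timedelta(days=1))
    return mid.dt.year, mid.dt.month


def collate_tubes(
    raw: pd.DataFrame,
    timescale: str = SHORT,
    return_report: bool = False,
):
    """Collate raw track-tube checks into per-plot-period occupancy statistics.

    ``k`` is the modal per-subplot check count within the period; subplots
    whose count deviates from the mode by more than one check are listed in
    the optional collation report.
    """
    _check_timescale(timescale)
    _reject_already_collated(raw, ["s", "s_star", "d", "k"])
    missing = _RAW_TUBE_COLS - set(raw.columns)
    if missing:
        raise ValueError(f"raw tube records missing columns: {sorted(missing)}")
    df = raw.copy()
    if df["subplot_id"].isna().any() or (df["subplot_id"].astype(str) == "").any():
        raise ValueError("missing subplot_id in tube records")
    start = pd.to_datetime(df["check_start_date"])
    end = pd.to_datetime(df["check_end_date"])
    if (end < start).any():
        raise ValueError("tube check interval with end before start")
    _, df["month"] = _midpoint_month(start, end)
    df = _drop_inactive_months(df, df["month"], "tube-check")
    if df.empty:
        cols = OCCUPANCY_SUMMARY_COLS
        empty = pd.DataFrame(columns=cols)
        return (empty, pd.DataFrame()) if return_report else empty

    group = ["plot_id", "year", "month"] if timescale == SHORT else ["plot_id", "year"]
    per_sub = (
        df.groupby(group + ["subplot_id"])["detected"]
        .agg(checks="size", dets="sum")
        .reset_index()
    )
    rows, flagged = [], []
    for key, g in per_sub.groupby(group, sort=True):
        k = int(g["checks"].mode().iloc[0])
        dev = g[(g["checks"] - k).abs() > 1]
        for _, r in dev.iterrows():
            flagged.append({**dict(zip(group, key if isinstance(key, tuple) else (key,))),
                            "subplot_id": r["subplot_id"],
                            "checks": int(r["checks"]), "modal_k": k})
        row = dict(zip(group, key if isinstance(key, tuple) else (key,)))
        row.setdefault("month", pd.NA)
        rows.append({**row,
                     "s": int(len(g)),
                     "s_star": int((g["dets"] > 0).sum()),
                     "d": int(g["dets"].sum()),
                     "k": k})
    res = pd.DataFrame(rows, columns=OCCUPANCY_SUMMARY_COLS)
    res["month"] = res["month"].astype("Int64")
    if flagged:
        warnings.warn(
            f"{len(flagged)} subplot(s) deviate from the modal check count "
            "by more than one check (see collation report)",
            stacklevel=2,
        )
    validate_occupancy_summary(res, timescale, strict=not flagged)
    report = pd.DataFrame(flagged)
    return (res, report) if return_report else res


def attach_registry(summary: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """Join subpopulation and selection covariate X onto a summary table."""
    unknown = set(summary["plot_id"]) - set(registry["plot_id"])
    if unknown:
        raise ValueError(f"plots absent from registry: {sorted(unknown)}")
    return summary.merge(registry[["plot_id", "subpopulation", "X"]], on="plot_id",
                         how="left")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_capture_summary(df: pd.DataFrame, timescale: str = SHORT) -> None:
    _check_timescale(timescale)
    missing = set(CAPTURE_SUMMARY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"capture summary missing columns: {sorted(missing)}")
    if df.empty:
        return
    M, n, t = df["M"].to_numpy(), df["n"].to_numpy(), df["t"].to_numpy()
    if (t < 1).any():
        raise ValueError("capture summary with t < 1")
    if (M < 0).any() or (n < M).any() or (n > M * t).any():
        raise ValueError("capture summary violates 0 <= M <= n <= M*t")
    has_month = df["month"].notna()
    if timescale == SHORT and not has_month.all():
        raise ValueError("short-timescale summaries require a month")
    if timescale == LONG and has_month.any():
        raise ValueError("long-timescale summaries must not carry a month")
    keys = df[["plot_id", "year", "month"]].astype(str)
    if keys.duplicated().any():
        raise ValueError("duplicate plot-period keys in capture summary")


def validate_occupancy_summary(df: pd.DataFrame, timescale: str = SHORT,
                               strict: bool = True) -> None:
    _check_timescale(timescale)
    missing = set(OCCUPANCY_SUMMARY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"occupancy summary missing columns: {sorted(missing)}")
    if df.empty:
        return
    s, ss, d, k = (df[c].to_numpy() for c in ["s", "s_star", "d", "k"])
    if (k < 1).any():
        raise ValueError("occupancy summary with k < 1")
    if (ss < 0).any() or (ss > s).any():
        raise ValueError("occupancy summary violates 0 <= s_star <= s")
    bad = (d < ss) | (d > ss * k)
    if bad.any():
        msg = "occupancy summary violates s_star <= d <= s_star*k"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (unequal per-subplot check counts)", stacklevel=2)
    has_month = df["month"].notna()
    if timescale == SHORT and not has_month.all():
        raise ValueError("short-timescale summaries require a month")
    if timescale == LONG and has_month.any():
        raise ValueError("long-timescale summaries must not carry a month")
    keys = df[["plot_id", "year", "month"]].astype(str)
    if keys.duplicated().any():
        raise ValueError("duplicate plot-period keys in occupancy summary")


# ---------------------------------------------------------------------------
# home-range diameter
# ---------------------------------------------------------------------------

def estimate_homerange_diameter(raw: pd.DataFrame, L: float = 37.5) -> HomeRangeSpec:
    """Estimate the home-range diameter from trap coordinates.

    For every individual captured at least twice, the statistic is the
    maximum pairwise distance between its capture locations; ``mean_d`` is
    the mean of these maxima and ``sd_d`` their standard error (treated as
    uncertainty in the mean diameter).
    """
    if not {"x_m", "y_m"} <= set(raw.columns):
        raise ValueError("coordinates x_m/y_m required to estimate home range; "
                         "use the configured defaults instead")
    caught = raw[(raw["individual_id"].fillna("") != "") & (raw["captured"] == 1)]
    caught = caught.dropna(subset=["x_m", "y_m"])
    maxima = []
    for _, g in caught.groupby("individual_id"):
        pts = g[["x_m", "y_m"]].to_numpy(float)
        if len(pts) >= 2:
            maxima.append(pdist(pts).max())
    if not maxima:
        raise ValueError(
            "no individuals captured at least twice with coordinates; "
            "use the configured default HomeRangeSpec"
        )
    maxima = np.asarray(maxima, float)
    if len(maxima) == 1:
        warnings.warn("single eligible individual; sd_d set to 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(maxima.std(ddof=1) / np.sqrt(len(maxima)))
    return HomeRangeSpec(mean_d=float(maxima.mean()), sd_d=sd, L=L)
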