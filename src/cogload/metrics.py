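"""Cognitive-load metrics per encounter trace, plus Tukey outlier analysis.

Four metrics proxy the effort a provider exerts in the EHR during one
encounter:

``n_loops``
    revisits of already-seen event types (total events minus distinct types);
``n_distinct``
    number of unique event types visited;
``duration_min``
    active time in minutes, summed across non-contiguous segments;
``avg_time_sec``
    mean dwell time per event in seconds, where the dwell of an event is the
    gap to the next event within its segment (segment-final events carry no
    dwell and are excluded).

Outliers are flagged with Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR) per
metric; a record is an outlier if any metric breaches its fence.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .audit_log import DEFAULT_GAP_MINUTES, EncounterTrace

METRIC_COLUMNS = ["n_loops", "n_distinct", "duration_min", "avg_time_sec"]

METRICS_CSV_COLUMNS = [
    "encounter_id",
    "provider_id",
    "n_loops",
    "n_distinct",
    "duration_min",
    "avg_time_sec",
    "outlier_any",
]


def _require_nonempty(trace: EncounterTrace) -> None:
    if len(trace) == 0:
        raise ValueError(f"encounter {trace.encounter_id}: empty trace")


def count_loops(trace: EncounterTrace, immediate_only: bool = False) -> int:
    """Number of revisits of already-seen event types.

    Default definition: every non-first occurrence of an event type is one
    loop, so loops = total events - distinct types (A,B,C,A,B,D -> 2).
    ``immediate_only=False`` is the default; setting it counts only revisits
    that are *not* immediate repeats of the previous event.
    """
    _require_nonempty(trace)
    types = trace.event_types.to_numpy()
    if not immediate_only:
        return int(len(types) - len(set(types)))
    seen: set[str] = set()
    loops = 0
    for i, t in enumerate(types):
        if t in seen and (i == 0 or types[i - 1] != t):
            loops += 1
        seen.add(t)
    return loops


def count_distinct_events(trace: EncounterTrace) -> int:
    """Cardinality of the set of event types visited during the encounter."""
    _require_nonempty(trace)
    return int(trace.event_types.nunique())


def _ts_seconds(trace: EncounterTrace) -> np.ndarray:
    return trace.timestamps.astype("datetime64[s]").astype("int64").to_numpy()


def encounter_duration(trace: EncounterTrace) -> float:
    """Active minutes: sum over segments of (last - first timestamp)."""
    _require_nonempty(trace)
    ts = _ts_seconds(trace)
    total = sum(ts[stop - 1] - ts[start] for start, stop in trace.segments)
    return float(total) / 60.0


def _segment_dwells(trace: EncounterTrace) -> np.ndarray:
    ts = _ts_seconds(trace)
    gaps = [np.diff(ts[start:stop]) for start, stop in trace.segments]
    if not gaps:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(gaps)


def avg_time_per_event(trace: EncounterTrace) -> float:
    """Mean within-segment dwell in seconds (0 for a single-event trace)."""
    _require_nonempty(trace)
    dwells = _segment_dwells(trace)
    if dwells.size == 0:
        return 0.0
    return float(dwells.mean())


def trace_metrics(trace: EncounterTrace, immediate_only: bool = False) -> dict:
    """All four metrics of one trace as a dict."""
    return {
        "encounter_id": trace.encounter_id,
        "n_loops": count_loops(trace, immediate_only=immediate_only),
        "n_distinct": count_distinct_events(trace),
        "duration_min": encounter_duration(trace),
        "avg_time_sec": avg_time_per_event(trace),
    }


def compute_metrics(
    events: pd.DataFrame,
    gap_minutes: float = DEFAULT_GAP_MINUTES,
    row_unit: Literal["provider_encounter", "encounter"] = "provider_encounter",
    per_provider_streams: bool = False,
) -> pd.DataFrame:
    """Vectorized metric table from a raw event DataFrame.

    With the default row unit, one row per (encounter, provider) pair. Each
    row carries the *combined* encounter trace's metrics — the total effort
    of the encounter — repeated for every involved provider, which is what
    encounter-clustered standard errors later absorb. With
    ``per_provider_streams=True`` each provider's row is computed from that
    provider's own events only.

    Equivalent to running the per-trace operations on every assembled
    trace; this path exists so millions of events stay fast.
    """
    if events.empty:
        raise ValueError("empty event log")
    keys = ["encounter_id"]
    if per_provider_streams:
        keys = ["encounter_id", "provider_id"]
    df = events.sort_values(keys + ["timestamp"], kind="stable")
    ts = df["timestamp"].astype("datetime64[s]").astype("int64").to_numpy()

    grp_codes = df.groupby(keys, sort=True).ngroup().to_numpy()
    same_grp = np.concatenate(([False], grp_codes[1:] == grp_codes[:-1]))
    gap_prev = np.diff(ts, prepend=ts[0]).astype(float)
    gap_prev[~same_grp] = np.nan
    within = same_grp & (gap_prev <= gap_minutes * 60.0)

    work = df[keys + ["event_type"]].copy()
    work["_dwell"] = np.where(
        np.concatenate((within[1:], [False]))
        & np.concatenate((grp_codes[1:] == grp_codes[:-1], [False])),
        np.concatenate((gap_prev[1:], [np.nan])),
        np.nan,
    )
    g = work.groupby(keys, sort=True)
    out = pd.DataFrame(
        {
            "n_events": g.size(),
            "n_distinct": g["event_type"].nunique(),
            "dwell_sum": g["_dwell"].sum(),
            "n_dwell": g["_dwell"].count(),
        }
    )
    out["n_loops"] = out["n_events"] - out["n_distinct"]
    out["duration_min"] = out["dwell_sum"] / 60.0
    out["avg_time_sec"] = np.where(
        out["n_dwell"] > 0, out["dwell_sum"] / out["n_dwell"].replace(0, 1), 0.0
    )
    out = out.reset_index()[
        keys + ["n_loops", "n_distinct", "duration_min", "avg_time_sec"]
    ]
    if row_unit == "encounter" and not per_provider_streams:
        return out
    if per_provider_streams:
        return out
    pairs = events[["encounter_id", "provider_id"]].drop_duplicates()
    merged = pairs.merge(out, on="encounter_id", how="left")
    return merged.sort_values(["encounter_id", "provider_id"], kind="stable").reset_index(
        drop=True
    )


class TukeyOutlierFlagger(TransformerMixin, BaseEstimator):
    """Flag per-metric outliers with Tukey fences.

    ``fit`` computes, for each metric column, the fences
    ``[Q1 - k*IQR, Q3 + k*IQR]`` (k=1.5, quartiles by linear interpolation,
    numpy's default rule); ``transform`` appends boolean ``outlier_<metric>``
    columns and ``outlier_any`` (their OR).

    Parameters
    ----------
    k : float
        Fence multiplier, 1.5 by default (the Tukey rule).
    columns : sequence of str
        Metric columns to fence; defaults to the four load metrics.
    """

    def __init__(self, k: float = 1.5, columns: tuple[str, ...] = tuple(METRIC_COLUMNS)):
        self.k = k
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "TukeyOutlierFlagger":
        if len(X) < 4:
            raise ValueError("need at least 4 records for well-defined quartiles")
        fences = {}
        for col in self.columns:
            vals = np.asarray(X[col], dtype=float)
            q1, q3 = np.quantile(vals, [0.25, 0.75])
            iqr = q3 - q1
            fences[col] = (q1 - self.k * iqr, q3 + self.k * iqr)
        self.fences_ = fences
        self.n_features_in_ = len(self.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "fences_")
        out = X.copy()
        any_flag = np.zeros(len(X), dtype=bool)
        for col, (lo, hi) in self.fences_.items():
            vals = np.asarray(X[col], dtype=float)
            flag = (vals < lo) | (vals > hi)
            out[f"outlier_{col}"] = flag
            any_flag |= flag
        out["outlier_any"] = any_flag
        return out


def tukey_flags(records: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper over :class:`TukeyOutlierFlagger`."""
    return TukeyOutlierFlagger(k=k).fit_transform(records)


def outlier_outcome_association(
    outlier_any: np.ndarray | pd.Series,
    initiated: np.ndarray | pd.Series,
) -> dict:
    """Association between outlier status and the binary outcome.

    Builds the 2x2 contingency of outlier_any x initiated and reports the
    Pearson chi-square p-value (no continuity correction), the risk ratio
    P(init | outlier) / P(init | non-outlier), and the odds ratio with a
    Woolf (log-OR normal approximation) 95% CI. Zero cells get the
    Haldane–Anscombe 0.5 correction for the OR and its CI.
    """
    flag = np.asarray(outlier_any, dtype=bool)
    y = np.asarray(initiated, dtype=int)
    if flag.all() or (~flag).all():
        raise ValueError("both outlier and non-outlier groups must be non-empty")
    # rows: outlier yes/no; cols: initiated yes/no
    a = int(((flag) & (y == 1)).sum())
    b = int(((flag) & (y == 0)).sum())
    c = int(((~flag) & (y == 1)).sum())
    d = int(((~flag) & (y == 0)).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    risk_out = a / (a + b)
    risk_non = c / (c + d)
    rr = risk_out / risk_non if risk_non > 0 else np.inf
    if min(a, b, c, d) == 0:
        warnings.warn(
            "zero cell in 2x2 table: applying Haldane–Anscombe 0.5 correction",
            stacklevel=2,
        )
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    or_ = (a_ * d_) / (b_ * c_)
    se_log_or = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(0.975)
    ci = (or_ * np.exp(-z * se_log_or), or_ * np.exp(z * se_log_or))
    return {
        "table": table,
        "chi2": float(chi2),
        "chi2_p": float(p),
        "risk_ratio": float(rr),
        "odds_ratio": float(or_),
        "or_ci95": (float(ci[0]), float(ci[1])),
        "rate_outlier": float(risk_out),
        "rate_non_outlier": float(risk_non),
    }
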