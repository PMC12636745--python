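"""Reading EHR audit-log event streams and assembling encounter traces.

An *encounter* is every audit-log event sharing an encounter id, regardless
of how much wall-clock time separates them: a provider may review a chart
briefly, see the patient later, and finish documentation after hours, and
all of that activity counts toward the same encounter's total effort.
Within an encounter, events are grouped into *segments* — maximal runs in
which no inter-event gap exceeds an inactivity threshold (30 minutes by
default). Only segment boundaries depend on the threshold; trace membership
never does.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Bit-exact CSV dialect for event logs.
EVENT_LOG_COLUMNS = [
    "encounter_id",
    "provider_id",
    "provider_role",
    "event_type",
    "timestamp",
]

#: Columns of the encounter-level covariate/outcome table.
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "patient_age",
    "patient_sex",
    "race_ethnicity",
    "insurance_class",
    "n_active_dx",
    "elixhauser",
    "initiated",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

DEFAULT_GAP_MINUTES = 30.0


class ProviderRole(str, enum.Enum):
    PHYSICIAN = "physician"
    NP = "NP"
    PA = "PA"


@dataclass(frozen=True)
class AuditEvent:
    """One timestamped user action tied to an encounter and provider."""

    encounter_id: str
    provider_id: str
    provider_role: str
    event_type: str
    timestamp: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.event_type:
            raise ValueError("event_type must be non-empty")


@dataclass
class EncounterTrace:
    """Ordered events of one encounter with its active segments.

    ``events`` is a DataFrame in event-log column order, stably sorted by
    timestamp (input order breaks ties). ``segments`` is a list of half-open
    ``(start, stop)`` index ranges partitioning the rows: consecutive gaps
    within a segment are <= the gap threshold, gaps between adjacent
    segments exceed it.
    """

    encounter_id: str
    events: pd.DataFrame
    segments: list[tuple[int, int]]
    provider_ids: frozenset[str] = field(default_factory=frozenset)
    gap_minutes: float = DEFAULT_GAP_MINUTES

    def __len__(self) -> int:
        return len(self.events)

    @property
    def event_types(self) -> pd.Series:
        return self.events["event_type"]

    @property
    def timestamps(self) -> pd.Series:
        return self.events["timestamp"]


@dataclass(frozen=True)
class EncounterMeta:
    """Patient covariates and the initiation outcome for one encounter."""

    encounter_id: str
    patient_age: float
    patient_sex: str
    race_ethnicity: str
    insurance_class: str
    n_active_dx: int
    elixhauser: int
    initiated: int

    def __post_init__(self) -> None:
        if not 20 <= self.patient_age <= 75:
            raise ValueError(f"patient_age {self.patient_age} outside [20, 75]")
        if self.n_active_dx < 1:
            raise ValueError("n_active_dx must be >= 1")


class EventLogError(ValueError):
    """Malformed event-log input (bad header, unparseable row)."""


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read an audit-log CSV into a validated event DataFrame.

    The header must match :data:`EVENT_LOG_COLUMNS` exactly; timestamps are
    ISO-8601 ``YYYY-MM-DDTHH:MM:SS``. Malformed rows fail fast with their
    1-based line number rather than being skipped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_LOG_COLUMNS:
        raise EventLogError(
            f"{path}: header {list(df.columns)!r} does not match "
            f"required columns {EVENT_LOG_COLUMNS!r}"
        )
    ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    bad = ts.isna()
    if bad.any():
        # +2: one for the header line, one for 1-based numbering.
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise EventLogError(
            f"{path}: unparseable timestamp "
            f"{df['timestamp'].iloc[line - 2]!r} on line {line}"
        )
    empty = df["event_type"].str.len() == 0
    if empty.any():
        line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
        raise EventLogError(f"{path}: empty event_type on line {line}")
    out = df.copy()
    out["timestamp"] = ts.astype("datetime64[s]")
    return out


def read_encounter_table(path: str | Path) -> pd.DataFrame:
    """Read the encounter-level covariate/outcome CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"{path}: missing encounter columns {missing}")
    return df


def write_event_log(events: pd.DataFrame, path: str | Path) -> Path:
    """Write events in the canonical CSV dialect (round-trip safe)."""
    path = Path(path)
    out = events[EVENT_LOG_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)
    return path


def events_from_records(records: Iterable[AuditEvent]) -> pd.DataFrame:
    """Build an event DataFrame from :class:`AuditEvent` records."""
    rows = [
        (e.encounter_id, e.provider_id, e.provider_role, e.event_type, e.timestamp)
        for e in records
    ]
    df = pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).astype("datetime64[s]")
    return df


def _segment_bounds(ts_seconds: np.ndarray, gap_seconds: float) -> list[tuple[int, int]]:
    """Half-open segment ranges: split where the inter-event gap exceeds the threshold."""
    n = len(ts_seconds)
    if n == 0:
        return []
    gaps = np.diff(ts_seconds)
    breaks = np.flatnonzero(gaps > gap_seconds) + 1
    edges = np.concatenate(([0], breaks, [n]))
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def assemble_encounters(
    events: pd.DataFrame | Sequence[AuditEvent],
    gap_minutes: float = DEFAULT_GAP_MINUTES,
) -> list[EncounterTrace]:
    """Group events by encounter id and segment each trace.

    Events are stably sorted by timestamp (ties keep input order); a new
    segment starts whenever the gap to the previous event exceeds
    ``gap_minutes``. Empty input yields an empty list.
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    if not isinstance(events, pd.DataFrame):
        events = events_from_records(events)
    if events.empty:
        return []
    gap_seconds = gap_minutes * 60.0
    traces: list[EncounterTrace] = []
    for enc_id, grp in events.groupby("encounter_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        ts = grp["timestamp"].astype("datetime64[s]").astype("int64").to_numpy()
        traces.append(
            EncounterTrace(
                encounter_id=str(enc_id),
                events=grp,
                segments=_segment_bounds(ts, gap_seconds),
                provider_ids=frozenset(grp["provider_id"].unique()),
                gap_minutes=gap_minutes,
            )
        )
    return traces
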