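import numpy as np
import pandas as pd
import pytest

from cogload.audit_log import assemble_encounters, events_from_records, AuditEvent
from cogload.simulate import SimConfig, generate_cohort


def make_events(
    types,
    times=None,
    encounter_id="E1",
    provider_id="P1",
    role="physician",
    start="2024-03-01T09:00:00",
):
    """Event DataFrame for one encounter from event types and offsets (seconds)."""
    if times is None:
        times = list(range(0, 10 * len(types), 10))
    base = pd.Timestamp(start)
    rows = [
        (encounter_id, provider_id, role, t, base + pd.Timedelta(seconds=int(s)))
        for t, s in zip(types, times)
    ]
    df = pd.DataFrame(
        rows,
        columns=["encounter_id", "provider_id", "provider_role", "event_type", "timestamp"],
    )
    df["timestamp"] = df["timestamp"].astype("datetime64[s]")
    return df


def make_trace(types, times=None, gap_minutes=30.0, **kwargs):
    """Single EncounterTrace from event types and second offsets."""
    events = make_events(types, times, **kwargs)
    (trace,) = assemble_encounters(events, gap_minutes=gap_minutes)
    return trace


def random_trace(rng, n_events=None, n_types=12, encounter_id="E1", multi_segment=True):
    """Random trace: arbitrary types, mixed small and session-breaking gaps."""
    if n_events is None:
        n_events = int(rng.integers(1, 60))
    types = [f"T{int(k)}" for k in rng.integers(0, n_types, n_events)]
    gaps = rng.integers(1, 300, size=max(n_events - 1, 0))
    if multi_segment and n_events > 3:
        n_breaks = int(rng.integers(0, 3))
        for pos in rng.choice(n_events - 1, size=min(n_breaks, n_events - 1), replace=False):
            gaps[pos] = int(rng.integers(31 * 60, 600 * 60))
    times = np.concatenate(([0], np.cumsum(gaps)))
    return make_trace(types, times, encounter_id=encounter_id)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across fast tests."""
    cfg = SimConfig(n_encounters=400, n_providers=12, n_event_types=30, seed=11)
    events, meta = generate_cohort(cfg)
    return cfg, events, meta
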