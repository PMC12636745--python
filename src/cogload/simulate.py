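"""Synthetic audit-log cohort generator.

Emulates the statistical structure of a primary-care statin-eligibility
cohort observed through EHR audit logs: ~20k encounters, each a timestamped
event stream split into 1-3 active segments, touched by 1-3 providers, with
patient covariates and a binary statin-initiation outcome drawn from a
quadratic logistic model of the encounter's realized cognitive-load
metrics.

The default marginals are the published descriptive statistics of such a
cohort (distinct event types mean ~34, loops mean ~73, active duration mean
~38 min, ages 20-75 with mean ~59, ~45.5% initiation prevalence); the
default outcome coefficients are the published quadratic-logit estimates,
which place a U-shaped loop effect with vertex near 94 loops and an
inverted-U distinct-event effect with vertex near 18.

Only marginal distributions are published; the joint structure (how loops,
distinct events and duration co-vary) is this generator's construction:
distinct and loop counts are drawn first, total events = distinct + loops,
the event sequence contains each chosen type at least once, and per-event
dwell times are log-normal with the per-encounter mean set so the active
duration hits its target. The per-event dwell mean is therefore determined
by duration and event count rather than being a free dial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .audit_log import ENCOUNTER_COLUMNS, EVENT_LOG_COLUMNS, write_event_log

RACE_LEVELS = [
    "Non-Hispanic/Latinx White",
    "Black/African American",
    "Hispanic/Latino",
    "Asian",
    "Other",
]
SEX_LEVELS = ["Male", "Female"]
INSURANCE_LEVELS = ["commercial", "non-commercial"]
ROLE_LEVELS = ["physician", "NP", "PA"]


def _default_covariate_betas() -> dict[str, float]:
    # Published quadratic-logit covariate estimates (log-odds).
    return {
        "race:Black/African American": 1.967e-01,
        "race:Hispanic/Latino": 5.906e-01,
        "race:Asian": 4.425e-01,
        "race:Other": 6.839e-01,
        "patient_age": 1.023e-02,
        "sex:Female": -8.218e-02,
        "insurance:non-commercial": 5.738e-02,
        "n_active_dx": -4.879e-02,
        "elixhauser": -9.656e-03,
    }


@dataclass
class OutcomeModel:
    """Log-odds coefficients generating the initiation outcome.

    The six cognitive-load coefficients default to the published estimates:
    loops enter U-shaped (vertex -beta_loops / (2*beta_loops_sq) ~ 93.9),
    distinct events inverted-U (vertex ~ 17.9). ``intercept=None`` means
    "solve numerically for ``target_prevalence``" — no intercept is
    published.
    """

    beta_loops: float = -1.239e-02
    beta_loops_sq: float = 6.597e-05
    beta_distinct: float = 6.412e-02
    beta_distinct_sq: float = -1.787e-03
    beta_duration: float = 8.223e-03
    beta_avg_time: float = -5.017e-04
    covariate_betas: dict[str, float] = field(default_factory=_default_covariate_betas)
    provider_effect_sd: float = 0.3
    intercept: float | None = None
    target_prevalence: float = 0.455

    def validate(self) -> None:
        vals = [
            self.beta_loops,
            self.beta_loops_sq,
            self.beta_distinct,
            self.beta_distinct_sq,
            self.beta_duration,
            self.beta_avg_time,
            self.provider_effect_sd,
            *self.covariate_betas.values(),
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all outcome coefficients must be finite")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")


@dataclass
class CovariateDistributions:
    """Patient covariate marginals (defaults match the published cohort)."""

    age_mean: float = 58.8
    age_sd: float = 10.8
    age_bounds: tuple[float, float] = (20.0, 75.0)
    sex_probs: tuple[float, ...] = (0.507, 0.493)  # Male, Female
    race_probs: tuple[float, ...] = (0.539, 0.124, 0.141, 0.077, 0.119)
    insurance_probs: tuple[float, ...] = (0.793, 0.207)  # commercial first
    n_dx_mean: float = 6.26
    n_dx_sd: float = 3.3
    n_dx_max: int = 32
    elixhauser_mean: float = 1.56
    elixhauser_sd: float = 5.4
    elixhauser_bounds: tuple[int, int] = (-18, 58)


@dataclass
class TraceDistributions:
    """Encounter-trace marginals (defaults match the published cohort)."""

    distinct_mean: float = 33.7
    distinct_sd: float = 6.5
    distinct_bounds: tuple[int, int] = (5, 80)
    loops_mean: float = 73.2
    loops_sd: float = 36.8
    loops_max: int = 500
    duration_mean_min: float = 38.3
    duration_sd_min: float = 21.0
    duration_bounds_min: tuple[float, float] = (0.5, 250.0)
    segment_probs: tuple[float, ...] = (0.45, 0.40, 0.15)  # P(1), P(2), P(3) segments
    dwell_log_sd: float = 1.0
    provider_count_probs: tuple[float, ...] = (0.735, 0.235, 0.03)  # 1, 2, 3 providers
    role_probs: tuple[float, ...] = (0.8241, 0.1166, 0.0593)


@dataclass
class SimConfig:
    """Full generator configuration; defaults are the emulated cohort."""

    n_encounters: int = 20376
    n_providers: int = 50
    n_event_types: int = 120
    seed: int = 0
    gap_minutes: float = 30.0
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    covariates: CovariateDistributions = field(default_factory=CovariateDistributions)
    traces: TraceDistributions = field(default_factory=TraceDistributions)

    def validate(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        if self.n_providers < 2:
            raise ValueError("n_providers must be >= 2")
        if self.n_event_types < 2:
            raise ValueError("n_event_types must be >= 2")
        if self.gap_minutes <= 0:
            raise ValueError("gap_minutes must be positive")
        for name, probs in [
            ("sex_probs", self.covariates.sex_probs),
            ("race_probs", self.covariates.race_probs),
            ("insurance_probs", self.covariates.insurance_probs),
            ("segment_probs", self.traces.segment_probs),
            ("provider_count_probs", self.traces.provider_count_probs),
            ("role_probs", self.traces.role_probs),
        ]:
            arr = np.asarray(probs, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        self.outcome.validate()


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _negbin(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    var = sd * sd
    if var <= mean:  # fall back to Poisson when under-dispersed
        return rng.poisson(mean, size)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _draw_covariates(
    rng: np.random.Generator, cfg: SimConfig
) -> pd.DataFrame:
    cov = cfg.covariates
    n = cfg.n_encounters
    age = _truncated_normal(rng, cov.age_mean, cov.age_sd, *cov.age_bounds, size=n)
    sex = rng.choice(SEX_LEVELS, n, p=cov.sex_probs)
    race = rng.choice(RACE_LEVELS, n, p=cov.race_probs)
    insurance = rng.choice(INSURANCE_LEVELS, n, p=cov.insurance_probs)
    n_dx = np.clip(
        1 + _negbin(rng, cov.n_dx_mean - 1.0, cov.n_dx_sd, n), 1, cov.n_dx_max
    )
    elix = np.clip(
        np.rint(rng.normal(cov.elixhauser_mean, cov.elixhauser_sd, n)).astype(int),
        *cov.elixhauser_bounds,
    )
    return pd.DataFrame(
        {
            "patient_age": np.round(age, 1),
            "patient_sex": sex,
            "race_ethnicity": race,
            "insurance_class": insurance,
            "n_active_dx": n_dx,
            "elixhauser": elix,
        }
    )


def _covariate_linear_predictor(meta: pd.DataFrame, betas: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(meta))
    for key, beta in betas.items():
        if ":" in key:
            kind, level = key.split(":", 1)
            col = {"race": "race_ethnicity", "sex": "patient_sex", "insurance": "insurance_class"}[kind]
            lp += beta * (meta[col].to_numpy() == level)
        else:
            lp += beta * meta[key].to_numpy(dtype=float)
    return lp


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (event_log, encounter_table) for one synthetic cohort.

    Deterministic: identical config (including seed) yields byte-identical
    output. The outcome of each encounter is Bernoulli(logistic(lp)) where
    lp applies the outcome model to the encounter's *realized* metrics
    (after timestamps are rounded to whole seconds), the patient
    covariates, and the primary provider's fixed effect. The intercept is
    solved by root-finding so realized prevalence matches the target.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    tr = config.traces
    gap_sec = config.gap_minutes * 60.0

    enc_ids = np.array([f"E{i:06d}" for i in range(n)])
    meta = _draw_covariates(rng, config)

    # provider pool: roles fixed per provider
    prov_ids = np.array([f"P{i:03d}" for i in range(config.n_providers)])
    prov_roles = rng.choice(ROLE_LEVELS, config.n_providers, p=tr.role_probs)
    provider_effects = rng.normal(0.0, config.outcome.provider_effect_sd, config.n_providers)

    # per-encounter scalar draws
    max_distinct = min(tr.distinct_bounds[1], config.n_event_types)
    lo_d = min(tr.distinct_bounds[0], max_distinct)
    distinct = np.clip(
        np.rint(rng.normal(tr.distinct_mean, tr.distinct_sd, n)).astype(int),
        lo_d,
        max_distinct,
    )
    loops = np.clip(_negbin(rng, tr.loops_mean, tr.loops_sd, n), 0, tr.loops_max)
    n_events = distinct + loops
    n_seg = rng.choice(np.array([1, 2, 3]), n, p=tr.segment_probs)
    n_seg = np.minimum(n_seg, n_events)
    sigma = np.sqrt(np.log(1.0 + (tr.duration_sd_min / tr.duration_mean_min) ** 2))
    mu = np.log(tr.duration_mean_min) - 0.5 * sigma**2
    duration_target = np.clip(rng.lognormal(mu, sigma, n), *tr.duration_bounds_min)

    k_prov = rng.choice(np.array([1, 2, 3]), n, p=tr.provider_count_probs)
    k_prov = np.minimum(k_prov, config.n_providers)

    # encounter start times spread over one calendar year of workdays
    base = pd.Timestamp("2024-01-01 00:00:00").value // 10**9
    day = rng.integers(0, 365, n)
    start_sec = base + day * 86400 + rng.integers(7 * 3600, 17 * 3600, n)

    # per-encounter assembly
    seq_types = np.empty(int(n_events.sum()), dtype=np.int64)
    seq_ts = np.empty(int(n_events.sum()), dtype=np.int64)
    seq_prov = np.empty(int(n_events.sum()), dtype=np.int64)
    realized_duration = np.empty(n)
    realized_avg_time = np.empty(n)
    primary_provider = np.empty(n, dtype=np.int64)
    enc_providers: list[np.ndarray] = []
    pos = 0
    sd = tr.dwell_log_sd
    for i in range(n):
        ne, d, s, k = int(n_events[i]), int(distinct[i]), int(n_seg[i]), int(k_prov[i])
        types = rng.choice(config.n_event_types, d, replace=False)
        counts = np.ones(d, dtype=np.int64)
        if ne > d:
            counts += rng.multinomial(ne - d, np.full(d, 1.0 / d))
        seq = rng.permutation(np.repeat(types, counts))

        n_gaps = ne - s
        if n_gaps > 0:
            g_mean = duration_target[i] * 60.0 / n_gaps
            dwells = rng.lognormal(np.log(g_mean) - 0.5 * sd * sd, sd, n_gaps)
            dwells = np.clip(np.rint(dwells), 1, max(gap_sec - 60.0, 1.0)).astype(np.int64)
        else:
            dwells = np.empty(0, dtype=np.int64)

        gaps = np.empty(ne - 1, dtype=np.int64) if ne > 1 else np.empty(0, dtype=np.int64)
        if s > 1:
            cut = np.sort(rng.choice(ne - 1, s - 1, replace=False))
            seg_gap = np.rint(
                rng.uniform(config.gap_minutes + 5.0, 480.0, s - 1) * 60.0
            ).astype(np.int64)
            mask = np.zeros(ne - 1, dtype=bool)
            mask[cut] = True
            gaps[mask] = seg_gap
            gaps[~mask] = dwells
        else:
            gaps[:] = dwells

        ts = start_sec[i] + np.concatenate(([0], np.cumsum(gaps)))

        provs = rng.choice(config.n_providers, k, replace=False)
        prov_per_event = np.full(ne, provs[0], dtype=np.int64)
        if k > 1 and ne > 1:
            pcut = np.sort(rng.choice(ne - 1, min(k - 1, ne - 1), replace=False)) + 1
            blocks = np.split(np.arange(ne), pcut)
            for j, block in enumerate(blocks):
                prov_per_event[block] = provs[min(j, k - 1)]

        seq_types[pos : pos + ne] = seq
        seq_ts[pos : pos + ne] = ts
        seq_prov[pos : pos + ne] = prov_per_event
        pos += ne

        realized_duration[i] = dwells.sum() / 60.0
        realized_avg_time[i] = dwells.mean() if dwells.size else 0.0
        primary_provider[i] = provs[0]
        enc_providers.append(np.unique(prov_per_event))

    # outcome: quadratic logit on realized metrics + covariates + primary provider FE
    om = config.outcome
    lp = (
        om.beta_loops * loops
        + om.beta_loops_sq * loops.astype(float) ** 2
        + om.beta_distinct * distinct
        + om.beta_distinct_sq * distinct.astype(float) ** 2
        + om.beta_duration * realized_duration
        + om.beta_avg_time * realized_avg_time
        + _covariate_linear_predictor(meta, om.covariate_betas)
        + provider_effects[primary_provider]
    )
    if om.intercept is None:
        intercept = solve_intercept(lp, om.target_prevalence)
    else:
        intercept = om.intercept
    p = expit(lp + intercept)
    initiated = rng.binomial(1, p)

    encounter_table = meta.copy()
    encounter_table.insert(0, "encounter_id", enc_ids)
    encounter_table["initiated"] = initiated
    encounter_table = encounter_table[ENCOUNTER_COLUMNS]

    event_log = pd.DataFrame(
        {
            "encounter_id": np.repeat(enc_ids, n_events),
            "provider_id": prov_ids[seq_prov],
            "provider_role": prov_roles[seq_prov],
            "event_type": np.array(
                [f"EVT_{t:03d}" for t in range(config.n_event_types)]
            )[seq_types],
            "timestamp": pd.to_datetime(seq_ts, unit="s").astype("datetime64[s]"),
        }
    )
    return event_log, encounter_table


def solve_intercept(lp_without_intercept: np.ndarray, prevalence: float) -> float:
    """Root-find the intercept making mean(expit(lp + c)) equal ``prevalence``."""

    def f(c: float) -> float:
        return float(expit(lp_without_intercept + c).mean() - prevalence)

    return float(brentq(f, -30.0, 30.0, xtol=1e-10))


def write_fixture(
    event_log: pd.DataFrame, encounter_table: pd.DataFrame, directory: str | Path
) -> dict[str, Path]:
    """Write the cohort as CSV fixtures; round-trips through ingestion."""
    if event_log.empty or encounter_table.empty:
        raise ValueError("refusing to write empty fixtures")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events_path = write_event_log(event_log, directory / "events.csv")
    enc_path = directory / "encounters.csv"
    encounter_table[ENCOUNTER_COLUMNS].to_csv(enc_path, index=False)
    return {"events": events_path, "encounters": enc_path}


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict form of a config (for YAML/JSON serialization)."""
    return asdict(config)
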