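"""Seeded synthetic ICU-stay generator.

Emulates the statistical structure a post-ICU-discharge deterioration study
assumes: two per-day latent factors (acute severity and physiologic
reserve/frailty), daily-sampled vital/lab/treatment channels read out from
them with channel-specific noise and missingness (MCAR or MNAR), planted
cohort-exclusion cases, planned readmission intervals, and a 7-day
deterioration outcome drawn from a logistic model on the latent risk at
discharge.  Real EHR extracts are credentialed; every downstream
stage of the package is exercised against this generator instead.

Time is measured in days (floats).  ``icu_in``/``icu_out``/event timestamps
share one absolute axis per cohort; CSV export renders them as ISO-8601
datetimes anchored at 2020-01-01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.optimize import brentq

__all__ = [
    "ChannelSpec",
    "SimConfig",
    "Readmission",
    "StayRecord",
    "ConfigError",
    "default_channels",
    "default_config",
    "site_shifted_config",
    "generate_cohort",
    "oracle_auroc",
    "expected_outcome_rate",
    "write_cohort",
    "read_cohort",
]

CSV_EPOCH = pd.Timestamp("2020-01-01")

GENERAL_WARD = "general-ward"
ADMISSION_SOURCES = ("emergency", "ward", "other-hospital", "operating-room")
DESTINATIONS = (GENERAL_WARD, "specialized-unit", "operating-room")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class ChannelSpec:
    """One time-varying channel of the simulated record.

    ``weight``/``frailty_weight`` are the loadings of the channel's
    z-scored value on the latent acuity and reserve/frailty factors;
    ``value = base + scale * (weight * s_t + frailty_weight * f_t + noise)``.
    Treatment channels instead emit a daily binary flag
    ``1[s_t + eta > threshold]`` (acuity-driven) and are never missing.  ``modeling=False`` channels (blood gases) exist
    only for SWIFT extraction and are not candidates for the model's
    variable set.
    """

    name: str
    kind: Literal["numeric", "treatment"] = "numeric"
    base: float = 0.0
    scale: float = 1.0
    weight: float = 0.0
    frailty_weight: float = 0.0
    noise_sd: float = 0.8
    missing_rate: float = 0.0
    mechanism: Literal["mcar", "mnar"] = "mcar"
    mnar_beta: float = 0.0
    day1_missing: bool = False
    threshold: float = 2.5  # treatments only
    samples_per_day: int = 1
    clip: tuple[float | None, float | None] = (None, None)
    modeling: bool = True


@dataclass(frozen=True)
class SimConfig:
    n_stays: int = 2000
    seed: int = 0
    channels: tuple[ChannelSpec, ...] = ()
    latent_ar_coeff: float = 0.7
    outcome_coeff: float = 1.3
    outcome_frailty_coeff: float = 0.4
    outcome_intercept: float = -3.35
    age_coeff: float = 0.15
    age_mean: float = 66.0
    age_sd: float = 16.0
    male_frac: float = 0.56
    death_given_failure: float = 0.3
    planned_readmit_frac: float = 0.05
    under24h_frac: float = 0.04
    icu_death_frac: float = 0.05
    transfer_frac: float = 0.04
    under18_frac: float = 0.02
    los_lognormal_mu: float = 1.1
    los_lognormal_sigma: float = 0.6
    admission_source_probs: tuple[float, ...] = (0.5, 0.25, 0.15, 0.1)

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ConfigError("n_stays must be >= 1")
        if not 0 < self.latent_ar_coeff < 1:
            raise ConfigError("latent_ar_coeff must lie in (0, 1)")
        fracs = {
            "planned_readmit_frac": self.planned_readmit_frac,
            "under24h_frac": self.under24h_frac,
            "icu_death_frac": self.icu_death_frac,
            "transfer_frac": self.transfer_frac,
            "under18_frac": self.under18_frac,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        excl = (self.under24h_frac + self.icu_death_frac
                + self.transfer_frac + self.under18_frac)
        if excl > 1:
            raise ConfigError("exclusion fractions sum above 1")
        if not self.channels:
            raise ConfigError("channels must be non-empty")
        for ch in self.channels:
            if not 0 <= ch.missing_rate <= 1:
                raise ConfigError(f"channels[{ch.name}].missing_rate must lie in [0, 1]")
            if ch.kind not in ("numeric", "treatment"):
                raise ConfigError(f"channels[{ch.name}].kind unknown")


@dataclass
class Readmission:
    """A return to the ICU after the index discharge.

    Planned returns carry their own interval end and event stream so the
    cohort stage can merge them into one continuous stay; unplanned returns
    are outcome events and carry only their start time.
    """

    time_in: float
    planned: bool
    time_out: float | None = None
    events: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class StayRecord:
    """One ICU stay: metadata, event stream, and outcome-relevant timestamps."""

    stay_id: str
    age: float
    sex: int  # 1 = male
    admission_source: str
    icu_in: float
    icu_out: float
    events: list[tuple[str, float, float]]
    discharge_destination: str = GENERAL_WARD
    death_time: float | None = None
    readmissions: list[Readmission] = field(default_factory=list)
    latent_severity: np.ndarray | None = None  # per-day truth, simulation only
    sim_category: str | None = None  # plant bookkeeping, simulation only

    @property
    def los_days(self) -> float:
        return self.icu_out - self.icu_in


def default_channels() -> tuple[ChannelSpec, ...]:
    """The packaged channel roster.

    Twenty-three modeling channels (6 treatments, 6 physiologic signals,
    9 labs, GCS, SAS) mirror a typical ICU daily-collection panel; together
    with age, sex and length of stay they form a 26-variable feature set.
    One decoy lab (lactate) is configured at 60% missingness so the <50%
    variable filter has something real to drop, and three labs are
    structurally unobserved on the first ICU day (orders placed from day 2)
    to exercise the no-history imputation path.  Blood-gas channels are
    emitted for SWIFT extraction only.
    """
    t = lambda name, thr: ChannelSpec(name, kind="treatment", threshold=thr)
    n = ChannelSpec
    return (
        t("hfnc", 2.2),
        t("ventilator", 2.4),
        t("dialysis", 2.9),
        t("vasopressor", 2.5),
        t("sedation", 2.0),
        t("transfusion", 2.3),
        n("mbp", base=87, scale=11, weight=-0.45, missing_rate=0.25, samples_per_day=3),
        n("hr", base=83, scale=14, weight=0.55, missing_rate=0.25, samples_per_day=3),
        n("rr", base=19.4, scale=3.5, weight=0.6, missing_rate=0.25, samples_per_day=3),
        n("bt", base=36.8, scale=0.45, weight=-0.2, frailty_weight=-0.3, noise_sd=0.9, missing_rate=0.30, samples_per_day=2),
        n("spo2", base=97.5, scale=1.8, weight=-0.5, missing_rate=0.25,
          samples_per_day=3, clip=(None, 100.0)),
        n("urine_output", base=1400, scale=600, weight=-0.65, frailty_weight=-0.5, missing_rate=0.35, clip=(0.0, None)),
        n("hco3", base=23, scale=3.8, weight=-0.35, noise_sd=0.85, missing_rate=0.45,
          mechanism="mnar", mnar_beta=0.7),
        n("wbc", base=9.5, scale=3.6, weight=0.6, missing_rate=0.25,
          mechanism="mnar", mnar_beta=0.7, day1_missing=True, clip=(0.5, None)),
        n("hemoglobin", base=10.2, scale=1.7, weight=-0.4, frailty_weight=-0.55, noise_sd=0.85, missing_rate=0.45),
        n("platelet", base=185, scale=80, weight=-0.25, frailty_weight=-0.45, noise_sd=0.9, missing_rate=0.45,
          clip=(5.0, None)),
        n("glucose", base=122, scale=38, weight=0.35, noise_sd=0.9, missing_rate=0.45),
        n("bun", base=19, scale=12, weight=0.9, frailty_weight=0.35, noise_sd=0.7, missing_rate=0.25,
          mechanism="mnar", mnar_beta=0.8, day1_missing=True, clip=(1.0, None)),
        n("creatinine", base=0.85, scale=0.55, weight=0.6, frailty_weight=0.35, missing_rate=0.25,
          mechanism="mnar", mnar_beta=0.8, day1_missing=True, clip=(0.1, None)),
        n("sodium", base=139, scale=4, weight=-0.2, noise_sd=0.95, missing_rate=0.45),
        n("potassium", base=3.85, scale=0.5, weight=0.25, noise_sd=0.95, missing_rate=0.45),
        n("gcs", base=14.3, scale=1.8, weight=-1.0, noise_sd=0.6, missing_rate=0.20,
          clip=(3.0, 15.0)),
        n("sas", base=4.0, scale=0.55, weight=-0.5, frailty_weight=-0.4, missing_rate=0.35, clip=(1.0, 7.0)),
        # decoy: real signal, but too sparse to survive the <50% filter
        n("lactate", base=1.8, scale=1.0, weight=0.7, missing_rate=0.60, clip=(0.2, None)),
        # SWIFT-only blood gases, never modeling candidates
        n("pao2", base=95, scale=25, weight=-0.6, missing_rate=0.70, clip=(40.0, None),
          modeling=False),
        n("paco2", base=40, scale=7, weight=0.3, missing_rate=0.70, clip=(15.0, None),
          modeling=False),
        n("fio2", base=0.30, scale=0.12, weight=0.4, missing_rate=0.75, clip=(0.21, 1.0),
          modeling=False),
    )


def default_config(n_stays: int = 2000, seed: int = 0, **overrides) -> SimConfig:
    return replace(SimConfig(n_stays=n_stays, seed=seed, channels=default_channels()),
                   **overrides)


def site_shifted_config(base: SimConfig, n_stays: int, seed: int) -> SimConfig:
    """A distribution-shifted 'external hospital' variant of ``base``.

    Shifts channel baselines by ~0.35 channel-SD, inflates lab missingness,
    ages the population, raises outcome prevalence, and — most importantly —
    moves the outcome weights from the acuity factor toward the reserve/
    frailty factor.  A model trained at the source site has learned mostly
    the acuity direction, so it transfers with a real performance drop that
    site data can gradually repair: exactly the setting fine-tuning
    experiments are about.
    """
    shifted = []
    for i, ch in enumerate(base.channels):
        if ch.kind == "numeric":
            direction = 1.0 if i % 2 == 0 else -1.0
            miss = min(0.48, ch.missing_rate * 1.15) if 0 < ch.missing_rate < 0.5 \
                else ch.missing_rate
            shifted.append(replace(ch, base=ch.base + direction * 0.35 * ch.scale,
                                   missing_rate=miss))
        else:
            shifted.append(replace(ch, threshold=ch.threshold - 0.2))
    return replace(base, n_stays=n_stays, seed=seed, channels=tuple(shifted),
                   age_mean=72.0, outcome_intercept=base.outcome_intercept + 0.35,
                   outcome_coeff=1.0, outcome_frailty_coeff=1.3,
                   los_lognormal_mu=base.los_lognormal_mu + 0.1)


def _mnar_intercept(rate: float, beta: float) -> float:
    """Intercept a such that E_z~N(0,1)[sigmoid(a + beta z)] = 1 - rate."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    w = weights / weights.sum()

    def marginal(a: float) -> float:
        return float(np.sum(w * expit(a + beta * nodes)))

    target = 1.0 - rate
    if target <= 0:
        return -50.0
    if target >= 1:
        return 50.0
    return brentq(lambda a: marginal(a) - target, -30, 30)


def _severity_path(rng: np.random.Generator, n_days: int, rho: float,
                   mu: float) -> np.ndarray:
    u = np.empty(n_days)
    u[0] = rng.standard_normal()
    innov = rng.standard_normal(n_days - 1) if n_days > 1 else np.empty(0)
    c = math.sqrt(1.0 - rho * rho)
    for t in range(1, n_days):
        u[t] = rho * u[t - 1] + c * innov[t - 1]
    return mu + u


def _channel_events(rng: np.random.Generator, ch: ChannelSpec,
                    acuity: np.ndarray, frailty: np.ndarray, day0: float,
                    mnar_alpha: dict[tuple[float, float], float],
                    day_start: np.ndarray,
                    day_len: np.ndarray) -> list[tuple[str, float, float]]:
    """Events for one channel over the days covered by ``severity``.

    ``day_start``/``day_len`` give, per day index, the in-ICU subinterval
    (relative to ``day0``) measurements may fall into; ``day_len == 0``
    marks days the patient is out of the ICU (the gap before a planned
    return) and emits nothing.  Sampling times inside the actual in-ICU
    portion keeps realized missingness at the configured rate even on
    partial first/last days.
    """
    n_days = len(acuity)
    in_icu = day_len > 0
    events: list[tuple[str, float, float]] = []
    if ch.kind == "treatment":
        eta = rng.normal(0.0, 0.6, n_days)
        flags = (acuity + eta > ch.threshold).astype(float)
        u = rng.uniform(0.05, 0.95, n_days)
        for t in range(n_days):
            if in_icu[t]:
                events.append((ch.name, float(day0 + day_start[t] + u[t] * day_len[t]),
                               float(flags[t])))
        return events

    k = max(1, ch.samples_per_day)
    noise = rng.normal(0.0, ch.noise_sd, (n_days, k))
    z = (ch.weight * acuity[:, None] + ch.frailty_weight * frailty[:, None]
         + noise)  # z-scored signal per sample
    values = ch.base + ch.scale * z
    lo, hi = ch.clip
    if lo is not None or hi is not None:
        values = np.clip(values, lo, hi)
    # observation decision is per day (daily collection panel)
    if ch.mechanism == "mnar" and ch.mnar_beta != 0.0:
        key = (ch.missing_rate, ch.mnar_beta)
        if key not in mnar_alpha:
            mnar_alpha[key] = _mnar_intercept(ch.missing_rate, ch.mnar_beta)
        day_sd = math.sqrt(ch.weight ** 2 + ch.frailty_weight ** 2
                           + ch.noise_sd ** 2 / k)
        p_obs = expit(mnar_alpha[key] + ch.mnar_beta * z.mean(axis=1) / day_sd)
    else:
        p_obs = np.full(n_days, 1.0 - ch.missing_rate)
    obs = rng.uniform(size=n_days) < p_obs
    if ch.day1_missing:
        obs[0] = False
    u = rng.uniform(0.02, 0.98, (n_days, k))
    for t in range(n_days):
        if obs[t] and in_icu[t]:
            for j in range(k):
                events.append((ch.name, float(day0 + day_start[t] + u[t, j] * day_len[t]),
                               float(values[t, j])))
    return events


def generate_cohort(config: SimConfig) -> list[StayRecord]:
    """Generate a seeded cohort of synthetic ICU stays.

    Deterministic given ``config``; planted exclusion categories are
    assigned (not sampled) so their counts are exact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    mnar_alpha: dict[tuple[float, float], float] = {}

    # --- assign planted categories by exact counts
    counts = {
        "under18": round(config.under18_frac * n),
        "under24h": round(config.under24h_frac * n),
        "icu_death": round(config.icu_death_frac * n),
        "transfer": round(config.transfer_frac * n),
    }
    order = rng.permutation(n)
    categories = np.array(["kept"] * n, dtype=object)
    pos = 0
    for cat, c in counts.items():
        categories[order[pos:pos + c]] = cat
        pos += c
    kept_idx = order[pos:]
    n_planned = round(config.planned_readmit_frac * len(kept_idx))
    planned = np.zeros(n, dtype=bool)
    planned[kept_idx[:n_planned]] = True

    stays: list[StayRecord] = []
    for i in range(n):
        cat = categories[i]
        if cat == "under18":
            age = float(rng.integers(1, 18))
        else:
            age = float(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 95))
        sex = int(rng.uniform() < config.male_frac)
        source = str(rng.choice(ADMISSION_SOURCES, p=config.admission_source_probs))
        icu_in = float(rng.uniform(0, 1000))

        if cat == "under24h":
            los = float(rng.uniform(0.15, 0.99))
        else:
            los = float(np.clip(rng.lognormal(config.los_lognormal_mu,
                                              config.los_lognormal_sigma), 1.05, 30.0))
        icu_out = icu_in + los

        has_planned = bool(planned[i]) and cat == "kept"
        gap = float(rng.uniform(0.5, 2.0)) if has_planned else 0.0
        ret_len = float(rng.uniform(1.05, 3.0)) if has_planned else 0.0
        total_span = los + gap + ret_len
        n_days = max(1, math.ceil(total_span))
        mu = config.age_coeff * (age - config.age_mean) / config.age_sd
        acuity = _severity_path(rng, n_days, config.latent_ar_coeff, mu)
        frailty = _severity_path(rng, n_days, config.latent_ar_coeff, 0.0)
        risk = config.outcome_coeff * acuity + config.outcome_frailty_coeff * frailty

        # per-day in-ICU subinterval (relative days); a planned-return stay
        # has two intervals, [0, los) and [los+gap, total_span)
        intervals = [(0.0, los)]
        if has_planned:
            intervals.append((los + gap, total_span))
        day_start = np.zeros(n_days)
        day_len = np.zeros(n_days)
        for t in range(n_days):
            best = (0.0, 0.0)
            for a, b in intervals:
                lo_t, hi_t = max(float(t), a), min(float(t + 1), b)
                if hi_t - lo_t > best[1]:
                    best = (lo_t, hi_t - lo_t)
            day_start[t], day_len[t] = best

        events: list[tuple[str, float, float]] = []
        for ch in config.channels:
            events.extend(_channel_events(rng, ch, acuity, frailty, icu_in,
                                          mnar_alpha, day_start, day_len))
        final_out = icu_in + total_span

        readmissions: list[Readmission] = []
        if has_planned:
            split = icu_in + los + gap
            return_events = [e for e in events if e[1] >= split]
            events = [e for e in events if e[1] < icu_out]
            readmissions.append(Readmission(time_in=split, planned=True,
                                            time_out=final_out, events=return_events))

        death_time: float | None = None
        destination = GENERAL_WARD
        if cat == "icu_death":
            death_time = icu_in + float(rng.uniform(0.3, 0.95)) * los
        elif cat == "transfer":
            destination = str(rng.choice(["specialized-unit", "operating-room"]))

        if cat == "kept":
            p = expit(config.outcome_intercept + risk[-1])
            if rng.uniform() < p:
                t_event = final_out + float(rng.uniform(1e-3, 7.0))
                if rng.uniform() < config.death_given_failure:
                    death_time = t_event
                else:
                    readmissions.append(Readmission(time_in=t_event, planned=False))

        stays.append(StayRecord(
            stay_id=f"stay-{i:05d}", age=age, sex=sex, admission_source=source,
            icu_in=icu_in, icu_out=icu_out, events=events,
            discharge_destination=destination, death_time=death_time,
            readmissions=readmissions, latent_severity=risk,
            sim_category=str(cat) if cat != "kept" else None))
    return stays


def expected_outcome_rate(config: SimConfig) -> float:
    """Closed-form expected deterioration rate under the generator's
    logistic outcome model and the stationary latent-risk distribution
    (marginally normal across stays; the acuity factor carries the
    age-linked mean shift)."""
    sd = math.sqrt(config.outcome_coeff ** 2 * (1.0 + config.age_coeff ** 2)
                   + config.outcome_frailty_coeff ** 2)
    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    w = weights / weights.sum()
    return float(np.sum(w * expit(config.outcome_intercept + sd * nodes)))


def oracle_auroc(stays: Sequence[StayRecord],
                 labels: Sequence[int] | None = None) -> float:
    """AUROC of the true discharge-day latent risk (the outcome model's
    linear predictor) against the realized labels — the Bayes-score ceiling
    a trained model is compared to."""
    from .cohort import label_outcome  # local import avoids a cycle
    from .evaluation import auroc

    for s in stays:
        if s.latent_severity is None:
            raise ValueError(f"{s.stay_id} lacks latent severity; "
                             "oracle_auroc needs synthetic truth")
    scores = np.array([s.latent_severity[-1] for s in stays])
    if labels is None:
        labels = np.array([label_outcome(s) for s in stays])
    return auroc(scores, np.asarray(labels))


# ---------------------------------------------------------------- CSV I/O

def _iso(t: float) -> str:
    return (CSV_EPOCH + pd.to_timedelta(t, unit="D")).isoformat()


def _from_iso(s) -> float | None:
    if s is None or (isinstance(s, float) and math.isnan(s)) or s == "":
        return None
    return float((pd.Timestamp(s) - CSV_EPOCH) / pd.Timedelta(days=1))


def write_cohort(stays: Iterable[StayRecord], out_dir: str | Path,
                 include_truth: bool = True) -> None:
    """Write a cohort as delimited text: ``stays.csv``, ``events.csv``,
    ``readmissions.csv`` and (optionally) ``truth.csv`` with the latent
    severity paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stay_rows, event_rows, readm_rows, truth_rows = [], [], [], []
    for s in stays:
        stay_rows.append({
            "stay_id": s.stay_id, "age": s.age, "sex": s.sex,
            "admission_source": s.admission_source,
            "icu_in": _iso(s.icu_in), "icu_out": _iso(s.icu_out),
            "discharge_destination": s.discharge_destination,
            "death_time": _iso(s.death_time) if s.death_time is not None else "",
        })
        for ch, t, v in s.events:
            event_rows.append({"stay_id": s.stay_id, "channel": ch,
                               "time": _iso(t), "value": v, "interval": "primary"})
        for r in s.readmissions:
            readm_rows.append({
                "stay_id": s.stay_id, "time_in": _iso(r.time_in),
                "time_out": _iso(r.time_out) if r.time_out is not None else "",
                "planned": int(r.planned)})
            for ch, t, v in r.events:
                event_rows.append({"stay_id": s.stay_id, "channel": ch,
                                   "time": _iso(t), "value": v, "interval": "return"})
        if include_truth and s.latent_severity is not None:
            for d, v in enumerate(s.latent_severity):
                truth_rows.append({"stay_id": s.stay_id, "day": d, "severity": v})
    pd.DataFrame(stay_rows).to_csv(out / "stays.csv", index=False)
    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    pd.DataFrame(readm_rows).to_csv(out / "readmissions.csv", index=False)
    if include_truth and truth_rows:
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)


def read_cohort(in_dir: str | Path) -> list[StayRecord]:
    """Reconstruct StayRecords from :func:`write_cohort` output (or any
    long-format tables matching the same column contract)."""
    d = Path(in_dir)
    stays_df = pd.read_csv(d / "stays.csv", dtype={"stay_id": str},
                           keep_default_na=False)
    events_df = pd.read_csv(d / "events.csv", dtype={"stay_id": str})
    readm_path = d / "readmissions.csv"
    readm_df = (pd.read_csv(readm_path, dtype={"stay_id": str}, keep_default_na=False)
                if readm_path.exists() and readm_path.stat().st_size > 1
                else pd.DataFrame(columns=["stay_id", "time_in", "time_out", "planned"]))
    truth_path = d / "truth.csv"
    truth = {}
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, dtype={"stay_id": str})
        for sid, g in tdf.groupby("stay_id"):
            truth[sid] = g.sort_values("day")["severity"].to_numpy()

    ev_primary: dict[str, list] = {}
    ev_return: dict[str, list] = {}
    for row in events_df.itertuples(index=False):
        interval = getattr(row, "interval", "primary")
        bucket = ev_return if interval == "return" else ev_primary
        bucket.setdefault(row.stay_id, []).append(
            (row.channel, _from_iso(row.time), float(row.value)))

    readm_by_stay: dict[str, list[Readmission]] = {}
    for row in readm_df.itertuples(index=False):
        readm_by_stay.setdefault(row.stay_id, []).append(Readmission(
            time_in=_from_iso(row.time_in), planned=bool(int(row.planned)),
            time_out=_from_iso(row.time_out)))

    stays = []
    for row in stays_df.itertuples(index=False):
        readms = readm_by_stay.get(row.stay_id, [])
        ret_events = ev_return.get(row.stay_id, [])
        for r in readms:
            if r.planned and r.time_out is not None:
                r.events = [e for e in ret_events
                            if r.time_in <= e[1] < r.time_out]
        stays.append(StayRecord(
            stay_id=row.stay_id, age=float(row.age), sex=int(row.sex),
            admission_source=row.admission_source,
            icu_in=_from_iso(row.icu_in), icu_out=_from_iso(row.icu_out),
            events=sorted(ev_primary.get(row.stay_id, []), key=lambda e: e[1]),
            discharge_destination=row.discharge_destination,
            death_time=_from_iso(row.death_time),
            readmissions=readms,
            latent_severity=truth.get(row.stay_id)))
    return stays
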