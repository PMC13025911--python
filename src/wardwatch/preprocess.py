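"""Daily aggregation, variable selection, normalization, and fill imputation.

Raw event streams become per-stay daily-grid triples (values ``X``,
observation mask ``M``, days-since-last-observation ``Delta``) plus static
covariates and the endpoint label.  Day bins are 24 h windows anchored at
ICU admission; multiple measurements within a bin are averaged (numeric
channels) or OR-ed (treatment flags).  A bin is missing only when it holds
no measurement at all.  Channels are retained only when their pooled
missing rate over the training split is strictly below 50%; numeric
channels are z-scored with statistics fitted on the training split only.

Where ``M == 0``, ``X`` holds NaN as a sentinel.  Downstream consumers must
branch on ``M``, never on the sentinel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthetic import ChannelSpec, StayRecord

__all__ = ["StayTensor", "NormStats", "daily_aggregate", "compute_delta",
           "missing_rates", "filter_variables", "fit_normalization",
           "apply_normalization", "forward_mean_fill", "last_day_snapshot",
           "snapshot_matrix", "prepare_split", "save_tensors", "load_tensors"]


@dataclass
class StayTensor:
    """Per-stay daily grid: X/M/Delta share shape (T, D)."""

    stay_id: str
    X: np.ndarray        # daily values; NaN where M == 0
    M: np.ndarray        # 1 = observed
    Delta: np.ndarray    # days since the channel was last observed
    static: np.ndarray   # (age, sex)
    label: int
    channels: list[str]
    numeric: np.ndarray  # bool per channel; False = binary treatment
    day_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    normalized: bool = False
    latent_severity: np.ndarray | None = None  # synthetic truth, if any

    @property
    def n_days(self) -> int:
        return self.X.shape[0]

    @property
    def los_days(self) -> float:
        return float(self.day_times[-1] + 1) if len(self.day_times) else 0.0


@dataclass
class NormStats:
    """Per-channel moments over observed training entries only.

    ``mean``/``std`` use the population (divide-by-n) variance convention.
    Treatment channels are not normalized; their ``mean`` is the observed
    event rate, kept for mean-fill.  ``fill_value(normalized)`` is the
    global-mean imputation target in the requested space (0 for normalized
    numeric channels).
    """

    channels: list[str]
    mean: np.ndarray
    std: np.ndarray
    numeric: np.ndarray
    age_mean: float
    age_std: float

    def fill_values(self, normalized: bool) -> np.ndarray:
        if normalized:
            return np.where(self.numeric, 0.0, self.mean)
        return self.mean.copy()

    def to_dict(self) -> dict:
        return {"channels": self.channels, "mean": self.mean.tolist(),
                "std": self.std.tolist(), "numeric": self.numeric.tolist(),
                "age_mean": self.age_mean, "age_std": self.age_std}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(channels=list(d["channels"]), mean=np.asarray(d["mean"]),
                   std=np.asarray(d["std"]), numeric=np.asarray(d["numeric"], bool),
                   age_mean=float(d["age_mean"]), age_std=float(d["age_std"]))


def compute_delta(M: np.ndarray) -> np.ndarray:
    """Days since last observation on a daily grid.

    Delta[0, d] = 0; Delta[t, d] = 1 if M[t-1, d] == 1 else Delta[t-1, d] + 1.
    """
    M = np.asarray(M)
    T, D = M.shape
    delta = np.zeros((T, D))
    for t in range(1, T):
        delta[t] = np.where(M[t - 1] == 1, 1.0, delta[t - 1] + 1.0)
    return delta


def daily_aggregate(stay: StayRecord, channels: Sequence[ChannelSpec],
                    label: int = 0) -> StayTensor:
    """Bin one stay's events onto its admission-anchored daily grid.

    T = ceil(length of stay in days); bin t covers
    [icu_in + t, icu_in + t + 1) days.  Numeric channels average in-bin
    values; treatment channels flag any in-bin positive event.
    """
    T = max(1, math.ceil(stay.los_days - 1e-9))
    names = [c.name for c in channels]
    index = {n: i for i, n in enumerate(names)}
    numeric = np.array([c.kind == "numeric" for c in channels])
    sums = np.zeros((T, len(channels)))
    counts = np.zeros((T, len(channels)))
    flags = np.zeros((T, len(channels)))
    for ch, t, v in stay.events:
        if ch not in index:
            continue
        if not (stay.icu_in <= t <= stay.icu_out):
            raise ValueError(f"{stay.stay_id}: event at {t} outside the stay "
                             f"[{stay.icu_in}, {stay.icu_out}]")
        b = min(int((t - stay.icu_in) // 1.0), T - 1)
        d = index[ch]
        sums[b, d] += v
        counts[b, d] += 1
        if v != 0:
            flags[b, d] = 1.0
    M = (counts > 0).astype(float)
    with np.errstate(invalid="ignore"):
        X = np.where(M == 1, sums / np.where(counts == 0, 1, counts), np.nan)
    X = np.where(numeric[None, :], X, np.where(M == 1, flags, np.nan))
    return StayTensor(stay_id=stay.stay_id, X=X, M=M, Delta=compute_delta(M),
                      static=np.array([stay.age, float(stay.sex)]),
                      label=label, channels=names, numeric=numeric,
                      day_times=np.arange(T, dtype=float),
                      latent_severity=stay.latent_severity)


def missing_rates(tensors: Sequence[StayTensor]) -> np.ndarray:
    """Pooled per-channel missing rate over all stay-days."""
    obs = sum(t.M.sum(axis=0) for t in tensors)
    days = sum(t.n_days for t in tensors)
    return 1.0 - obs / days


def filter_variables(tensors: Sequence[StayTensor], max_missing: float = 0.5,
                     rates: np.ndarray | None = None,
                     ) -> tuple[list[StayTensor], list[str]]:
    """Restrict to channels whose pooled missing rate is strictly below
    ``max_missing``.  ``rates`` should come from the training split; when
    omitted they are computed from ``tensors`` itself."""
    if not tensors:
        raise ValueError("no tensors to filter")
    if rates is None:
        rates = missing_rates(tensors)
    keep = np.where(rates < max_missing)[0]
    if keep.size == 0:
        raise ValueError("no channel survives the missing-rate filter")
    kept_names = [tensors[0].channels[i] for i in keep]
    out = []
    for t in tensors:
        out.append(StayTensor(
            stay_id=t.stay_id, X=t.X[:, keep], M=t.M[:, keep],
            Delta=t.Delta[:, keep], static=t.static, label=t.label,
            channels=kept_names, numeric=t.numeric[keep],
            day_times=t.day_times, normalized=t.normalized,
            latent_severity=t.latent_severity))
    return out, kept_names


def fit_normalization(train_tensors: Sequence[StayTensor]) -> NormStats:
    """Per-channel mean/std over observed training entries (population
    variance convention).  Degenerate constant channels are rejected."""
    t0 = train_tensors[0]
    D = len(t0.channels)
    mean = np.zeros(D)
    std = np.ones(D)
    allX = np.concatenate([t.X for t in train_tensors], axis=0)
    allM = np.concatenate([t.M for t in train_tensors], axis=0)
    for d in range(D):
        vals = allX[allM[:, d] == 1, d]
        if vals.size == 0:
            raise ValueError(f"channel {t0.channels[d]} never observed in training data")
        mean[d] = vals.mean()
        if t0.numeric[d]:
            sd = vals.std()  # ddof=0
            if sd <= 0:
                raise ValueError(f"channel {t0.channels[d]} has zero variance")
            std[d] = sd
    ages = np.array([t.static[0] for t in train_tensors])
    age_sd = ages.std()
    if age_sd <= 0:
        raise ValueError("age has zero variance in the training split")
    return NormStats(channels=list(t0.channels), mean=mean, std=std,
                     numeric=t0.numeric.copy(), age_mean=float(ages.mean()),
                     age_std=float(age_sd))


def apply_normalization(tensors: Sequence[StayTensor],
                        stats: NormStats) -> list[StayTensor]:
    """Z-score numeric channels and age with training-split statistics.

    Treatment channels and sex pass through.  Re-application is refused
    (the ``normalized`` flag makes the pipeline non-idempotent on purpose).
    """
    out = []
    scale = np.where(stats.numeric, stats.std, 1.0)
    shift = np.where(stats.numeric, stats.mean, 0.0)
    for t in tensors:
        if t.normalized:
            raise ValueError(f"{t.stay_id}: tensor is already normalized")
        if t.channels != stats.channels:
            raise ValueError("channel list mismatch between tensor and NormStats")
        X = (t.X - shift) / scale
        static = t.static.copy()
        static[0] = (static[0] - stats.age_mean) / stats.age_std
        out.append(StayTensor(
            stay_id=t.stay_id, X=X, M=t.M.copy(), Delta=t.Delta.copy(),
            static=static, label=t.label, channels=t.channels,
            numeric=t.numeric, day_times=t.day_times, normalized=True,
            latent_severity=t.latent_severity))
    return out


def forward_mean_fill(tensor: StayTensor, stats: NormStats) -> np.ndarray:
    """Dense value matrix: carry the last observation forward; entries with
    no prior observation take the channel's global mean."""
    fill = stats.fill_values(tensor.normalized)
    T, D = tensor.X.shape
    out = np.empty((T, D))
    last = fill.copy()
    for t in range(T):
        m = tensor.M[t] == 1
        last = np.where(m, np.nan_to_num(tensor.X[t]), last)
        out[t] = last
    return out


def last_day_snapshot(filled: np.ndarray, tensor: StayTensor) -> np.ndarray:
    """Per-stay feature vector for non-temporal learners:
    (age, sex, final-day channel values, length of stay) — length D + 3."""
    return np.concatenate([tensor.static, filled[-1], [tensor.los_days]])


def snapshot_matrix(tensors: Sequence[StayTensor],
                    stats: NormStats) -> tuple[np.ndarray, np.ndarray]:
    """Stack last-day snapshots into (features, labels) arrays."""
    rows = [last_day_snapshot(forward_mean_fill(t, stats), t) for t in tensors]
    return np.vstack(rows), np.array([t.label for t in tensors])


def prepare_split(train_stays: Sequence[StayRecord], train_labels: Sequence[int],
                  test_stays: Sequence[StayRecord], test_labels: Sequence[int],
                  channels: Sequence[ChannelSpec], max_missing: float = 0.5,
                  ) -> tuple[list[StayTensor], list[StayTensor], NormStats, list[str]]:
    """Leakage-safe preprocessing: variable filter and normalization are
    fitted on the training split only, then applied to both splits."""
    modeling = [c for c in channels if c.modeling]
    train_t = [daily_aggregate(s, modeling, y) for s, y in zip(train_stays, train_labels)]
    test_t = [daily_aggregate(s, modeling, y) for s, y in zip(test_stays, test_labels)]
    rates = missing_rates(train_t)
    train_t, kept = filter_variables(train_t, max_missing, rates)
    test_t, _ = filter_variables(test_t, max_missing, rates)
    stats = fit_normalization(train_t)
    return (apply_normalization(train_t, stats),
            apply_normalization(test_t, stats), stats, kept)


# ------------------------------------------------------------- disk layout

def save_tensors(tensors: Sequence[StayTensor], stats: NormStats,
                 out_prefix: str | Path) -> None:
    """One array container per split (.npz) + JSON sidecar with the channel
    list and normalization statistics."""
    out_prefix = Path(out_prefix)
    arrays = {}
    meta = {"stay_ids": [], "labels": [], "normalized": [],
            "channels": tensors[0].channels if tensors else [],
            "norm_stats": stats.to_dict()}
    for i, t in enumerate(tensors):
        arrays[f"X_{i}"] = t.X
        arrays[f"M_{i}"] = t.M
        arrays[f"Delta_{i}"] = t.Delta
        arrays[f"static_{i}"] = t.static
        meta["stay_ids"].append(t.stay_id)
        meta["labels"].append(int(t.label))
        meta["normalized"].append(bool(t.normalized))
    np.savez(out_prefix.with_suffix(".npz"), **arrays)
    out_prefix.with_suffix(".json").write_text(json.dumps(meta))


def load_tensors(prefix: str | Path) -> tuple[list[StayTensor], NormStats]:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    stats = NormStats.from_dict(meta["norm_stats"])
    data = np.load(prefix.with_suffix(".npz"))
    tensors = []
    numeric = stats.numeric
    for i, sid in enumerate(meta["stay_ids"]):
        X = data[f"X_{i}"]
        tensors.append(StayTensor(
            stay_id=sid, X=X, M=data[f"M_{i}"], Delta=data[f"Delta_{i}"],
            static=data[f"static_{i}"], label=meta["labels"][i],
            channels=meta["channels"], numeric=numeric,
            day_times=np.arange(X.shape[0], dtype=float),
            normalized=meta["normalized"][i]))
    return tensors, stats
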