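"""Metrics, cross-validation, paired AUROC testing, and cohort statistics.

AUROC is the tie-aware pairwise probability P(score+ > score-) + P(tie)/2
(computed via mid-ranks); AUPR is average precision.  Model comparison uses
the fast structural-components (mid-rank) DeLong test.  Cross-validation is
stratified at the stay level with all preprocessing fitted inside each
training split.  The baseline-characteristics table reports median (IQR)
with Mann-Whitney U for numeric variables and count (%) with Fisher's exact
test for binary ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import StayTensor, NormStats, prepare_split
from .synthetic import ChannelSpec, StayRecord

__all__ = ["auroc", "aupr", "EvalReport", "ModelSpec", "RecurrentSpec",
           "SnapshotSpec", "SwiftSpec", "OracleSpec", "fold_assignments", "kfold_cv",
           "delong_test", "delong_components", "optimal_threshold",
           "trajectory_summary", "baseline_table"]


# ------------------------------------------------------------------ metrics

def _check_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-aware AUROC via mid-ranks (equals pairwise counting with half
    credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-wise precision at each positive's recall
    increment); random-score expectation is the prevalence."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("at least one positive required")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# ------------------------------------------------------------- EvalReport

@dataclass
class EvalReport:
    """Per-fold and aggregate ranking metrics for one model."""

    model: str
    fold_auroc: list[float]
    fold_aupr: list[float]
    seed: int
    mode: str = "internal-cv"  # or "zero-shot", "fine-tuned"
    paired_tests: list[dict] = field(default_factory=list)

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def auroc_std(self) -> float:
        return float(np.std(self.fold_auroc))

    @property
    def aupr_mean(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def aupr_std(self) -> float:
        return float(np.std(self.fold_aupr))

    def to_dict(self) -> dict:
        return {"model": self.model, "mode": self.mode, "seed": self.seed,
                "fold_auroc": self.fold_auroc, "fold_aupr": self.fold_aupr,
                "auroc_mean": self.auroc_mean, "auroc_std": self.auroc_std,
                "aupr_mean": self.aupr_mean, "aupr_std": self.aupr_std,
                "paired_tests": self.paired_tests}

    def summary(self) -> str:
        return (f"{self.model} [{self.mode}]: "
                f"AUROC {self.auroc_mean:.3f} (±{self.auroc_std:.3f}), "
                f"AUPR {self.aupr_mean:.3f} (±{self.aupr_std:.3f})")


# ----------------------------------------------------------- model specs

class ModelSpec(Protocol):
    """What k-fold CV needs from a model: fit on a training split, score a
    test split.  Both hooks see the raw stays and the leakage-safe tensors."""

    name: str

    def fit(self, stays, tensors, stats, seed: int): ...

    def score(self, fitted, stays, tensors, stats) -> np.ndarray: ...


class RecurrentSpec:
    def __init__(self, variant: str, config=None):
        from .models.training import TrainConfig
        self.name = variant
        self.variant = variant
        self.config = config or TrainConfig()

    def fit(self, stays, tensors, stats, seed):
        from .models.training import train
        from dataclasses import replace
        cfg = replace(self.config, seed=seed)
        params, _ = train(self.variant, tensors, cfg, stats)
        return params

    def score(self, fitted, stays, tensors, stats):
        from .models.training import predict
        return predict(fitted, self.variant, tensors, stats)


class SnapshotSpec:
    def __init__(self, name: str):
        self.name = name

    def fit(self, stays, tensors, stats, seed):
        from .models.baselines import fit_snapshot_model
        return fit_snapshot_model(self.name, tensors, stats, seed)

    def score(self, fitted, stays, tensors, stats):
        from .models.baselines import score_snapshot_model
        return score_snapshot_model(fitted, tensors, stats)


class SwiftSpec:
    name = "swift"

    def __init__(self, table=None):
        from .swift import DEFAULT_TABLE
        self.table = table or DEFAULT_TABLE

    def fit(self, stays, tensors, stats, seed):
        return self.table

    def score(self, fitted, stays, tensors, stats):
        from .swift import score_cohort
        return score_cohort(stays, fitted)


class OracleSpec:
    """Scores with the generator's true discharge-day severity; the
    training-free Bayes-score reference."""

    name = "oracle"

    def fit(self, stays, tensors, stats, seed):
        return None

    def score(self, fitted, stays, tensors, stats):
        return np.array([s.latent_severity[-1] for s in stays])


def fold_assignments(labels: Sequence[int], k: int,
                     seed: int) -> list[np.ndarray]:
    """Test-fold index sets: stratified k-fold in general; when k equals the
    number of stays, plain leave-one-out (stratification is impossible and
    each fold is a single stay)."""
    labels = np.asarray(labels)
    n = len(labels)
    if k == n:
        return [np.array([i]) for i in range(n)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [te for _, te in skf.split(np.zeros(n), labels)]


def kfold_cv(stays: Sequence[StayRecord], labels: Sequence[int],
             spec: ModelSpec, channels: Sequence[ChannelSpec], k: int = 10,
             seed: int = 0, max_missing: float = 0.5,
             mode: str = "internal-cv") -> EvalReport:
    """Stratified stay-level k-fold CV.

    Variable filter, normalization statistics and global means are fitted
    inside each training split only; the model's own selection split (10%
    of training data, for early stopping) lives inside ``spec.fit``.
    """
    labels = np.asarray(labels)
    stays = list(stays)
    if len(stays) < k:
        raise ValueError("need at least k stays")
    fold_auroc, fold_aupr = [], []
    all_idx = np.arange(len(stays))
    for fold, te in enumerate(fold_assignments(labels, k, seed)):
        if len(np.unique(labels[te])) < 2:
            raise ValueError(f"fold {fold}: only one class in the test fold")
        tr = np.setdiff1d(all_idx, te)
        train_stays = [stays[i] for i in tr]
        test_stays = [stays[i] for i in te]
        train_t, test_t, stats, _ = prepare_split(
            train_stays, labels[tr], test_stays, labels[te], channels, max_missing)
        fitted = spec.fit(train_stays, train_t, stats, seed=seed * 1000 + fold)
        scores = spec.score(fitted, test_stays, test_t, stats)
        fold_auroc.append(auroc(scores, labels[te]))
        fold_aupr.append(aupr(scores, labels[te]))
    return EvalReport(model=spec.name, fold_auroc=fold_auroc,
                      fold_aupr=fold_aupr, seed=seed, mode=mode)


# ------------------------------------------------------------ DeLong test

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x)


def delong_components(scores: np.ndarray, labels: np.ndarray,
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus the placement components (V10 over positives, V01 over
    negatives) of the structural-components decomposition."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    a = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(a), v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> dict:
    """Paired two-sided DeLong comparison of two correlated AUROCs.

    Variance of the AUROC difference from the paired placement components;
    p from the normal approximation.  Identical rankings give a degenerate
    flag and p = 1.
    """
    labels = np.asarray(labels)
    _check_classes(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or len(sa) != len(labels):
        raise ValueError("paired scores must share the stay axis")
    auc_a, v10_a, v01_a = delong_components(sa, labels)
    auc_b, v10_b, v01_b = delong_components(sb, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        return {"auroc_a": auc_a, "auroc_b": auc_b, "delta": delta,
                "z": 0.0, "p": 1.0, "degenerate": True}
    z = delta / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return {"auroc_a": auc_a, "auroc_b": auc_b, "delta": delta,
            "z": float(z), "p": float(p), "degenerate": False}


# ------------------------------------------------------------- thresholds

def optimal_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Operating threshold maximizing Youden's J (sensitivity + specificity
    - 1); predicted positive means score >= threshold.  Ties in J break
    toward the higher threshold (higher specificity); with perfect
    separation this returns the midpoint of the gap."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


# ---------------------------------------------------------- trajectories

def trajectory_summary(trajectories: Sequence[np.ndarray],
                       labels: Sequence[int],
                       align: str = "discharge") -> dict:
    """Group-mean risk curves with normal-approximation 95% bands.

    ``align='discharge'`` indexes days by offset from the final ICU day
    (0 = discharge day, -1 = the day before, ...); ``align='admission'``
    by day since admission.  Bands use mean ± 1.96 sd/sqrt(n) over the
    stays contributing to each offset; a single contributing stay gives a
    zero-width band and a degenerate flag.
    """
    if align not in ("admission", "discharge"):
        raise ValueError("align must be 'admission' or 'discharge'")
    labels = np.asarray(labels)
    out: dict = {"align": align, "groups": {}}
    for group, name in ((1, "failure"), (0, "success")):
        trajs = [t for t, y in zip(trajectories, labels) if y == group]
        if not trajs:
            raise ValueError(f"empty {name} group")
        buckets: dict[int, list[float]] = {}
        for t in trajs:
            T = len(t)
            for i, v in enumerate(t):
                off = i if align == "admission" else i - (T - 1)
                buckets.setdefault(off, []).append(float(v))
        offsets = sorted(buckets)
        mean = np.array([np.mean(buckets[o]) for o in offsets])
        counts = np.array([len(buckets[o]) for o in offsets])
        sd = np.array([np.std(buckets[o], ddof=1) if len(buckets[o]) > 1 else 0.0
                       for o in offsets])
        half = 1.96 * sd / np.sqrt(counts)
        out["groups"][name] = {
            "offsets": offsets, "mean": mean, "lower": mean - half,
            "upper": mean + half, "n": counts,
            "degenerate": bool((counts == 1).any())}
    return out


# ------------------------------------------------- baseline characteristics

def baseline_table(values: pd.DataFrame, group: Sequence[int],
                   binary: Sequence[str] = ()) -> pd.DataFrame:
    """Characteristics table comparing two groups.

    ``values``: one row per stay, one column per variable (NaN = missing).
    Numeric variables report median (IQR) per group with a two-sided
    Mann-Whitney U p-value; binary variables report count (%) with a
    two-sided Fisher's exact p-value.  A per-variable missing-rate column
    is included.  Variables absent in both groups are omitted with a
    warning row marker.
    """
    import warnings

    group = np.asarray(group)
    if (group == 1).sum() == 0 or (group == 0).sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in values.columns:
        v = values[col]
        miss = float(v.isna().mean())
        v1 = v[group == 1].dropna()
        v0 = v[group == 0].dropna()
        if len(v1) == 0 and len(v0) == 0:
            warnings.warn(f"variable {col} absent in both groups; omitted")
            continue
        if col in binary:
            a, b = int((v1 == 1).sum()), int((v1 == 0).sum())
            c, d = int((v0 == 1).sum()), int((v0 == 0).sum())
            _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            def fmt(pos, neg):
                n = pos + neg
                return f"{pos} ({100 * pos / n:.2f}%)" if n else "-"
            rows.append({"variable": col, "type": "binary",
                         "failure": fmt(a, b), "success": fmt(c, d),
                         "p_value": float(p), "missing_rate": miss})
        else:
            if len(v1) == 0 or len(v0) == 0:
                rows.append({"variable": col, "type": "numeric", "failure": "-",
                             "success": "-", "p_value": np.nan,
                             "missing_rate": miss})
                continue
            use_exact = (len(v1) <= 50 and len(v0) <= 50)
            res = sps.mannwhitneyu(v1, v0, alternative="two-sided",
                                   method="exact" if use_exact and
                                   len(np.unique(np.concatenate([v1, v0])))
                                   == len(v1) + len(v0) else "asymptotic")
            def fmt_num(x):
                q1, q2, q3 = np.percentile(x, [25, 50, 75])
                return f"{q2:.2f} ({q1:.2f}-{q3:.2f})"
            rows.append({"variable": col, "type": "numeric",
                         "failure": fmt_num(v1), "success": fmt_num(v0),
                         "p_value": float(res.pvalue), "missing_rate": miss})
    return pd.DataFrame(rows)
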