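"""Classifier performance metrics and Monte-Carlo comparisons.

Includes the prevalence-adjusted positive predictive value (PPV recomputed
by Bayes' rule at a stated baseline progression rate — 33.6% of MCI
patients progressing within 3 years is the meta-analytic default), a
parametric Bernoulli Monte-Carlo test for differences in classifier
performance, an exact binomial enrichment-over-baseline test, and ROC/AUC
comparison of the two-stage signature against standard classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PREVALENCE = 0.336
DEFAULT_REPS = 100_000

# one-sided directions for the high-specificity comparison: the signature is
# expected to gain accuracy/specificity/PPV and to lose sensitivity
DEFAULT_DIRECTIONS = {"accuracy": "greater", "specificity": "greater",
                      "ppv": "greater", "sensitivity": "less"}


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceMetrics:
    """Proportions in [0, 1]; NaN where the defining denominator is zero."""

    sensitivity: float
    specificity: float
    ppv: float
    accuracy: float
    adjusted_ppv: float = float("nan")
    prevalence: float = float("nan")

    def as_dict(self) -> dict:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "accuracy": self.accuracy,
                "adjusted_ppv": self.adjusted_ppv, "prevalence": self.prevalence}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(counts: ConfusionCounts,
                      prevalence: float | None = None) -> PerformanceMetrics:
    """Sensitivity, specificity, PPV, accuracy from a confusion matrix.

    Zero denominators yield NaN (undefined), never 0.  When ``prevalence``
    is given, the prevalence-adjusted PPV is filled in as well.
    """
    m = PerformanceMetrics(
        sensitivity=_safe_div(counts.tp, counts.tp + counts.fn),
        specificity=_safe_div(counts.tn, counts.tn + counts.fp),
        ppv=_safe_div(counts.tp, counts.tp + counts.fp),
        accuracy=_safe_div(counts.tp + counts.tn, counts.total),
    )
    if prevalence is not None:
        m.adjusted_ppv = adjusted_ppv(m.sensitivity, m.specificity, prevalence)
        m.prevalence = prevalence
    return m


def adjusted_ppv(sensitivity: float, specificity: float,
                 prevalence: float = DEFAULT_PREVALENCE) -> float:
    """PPV at a stated baseline prevalence, by Bayes' rule.

    ``sens * p / (sens * p + (1 - spec) * (1 - p))``.  Returns NaN when the
    denominator is zero (e.g. degenerate prevalence with no positive calls).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not np.isnan(v) and not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    return num / den if den > 0 else float("nan")


@dataclass
class PerfTestResult:
    p_values: dict[str, float]
    reps: int
    directions: dict[str, str]
    excluded: dict[str, int] = field(default_factory=dict)


def performance_difference_test(metrics_a: PerformanceMetrics,
                                metrics_b: PerformanceMetrics,
                                n_positive: int, n_negative: int,
                                reps: int = DEFAULT_REPS, seed: int = 0,
                                directions: dict[str, str] | None = None
                                ) -> PerfTestResult:
    """Bernoulli Monte-Carlo test of a performance difference.

    Model A's observed sensitivity and specificity define a parametric null:
    in each replication TP ~ Binomial(n_positive, sens_A) and
    FP ~ Binomial(n_negative, 1 - spec_A), from which replicated accuracy,
    PPV, specificity and sensitivity are derived.  The one-sided p-value for
    each metric is ``(1 + #{replications at least as extreme as B's observed
    value in the tested direction}) / (reps + 1)``.  Replications with an
    undefined PPV (no positive calls) are excluded from that metric's tail
    count and the exclusion count reported.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replications")
    if n_positive <= 0 or n_negative <= 0:
        raise ValueError("sample sizes must be positive")
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    rng = np.random.default_rng(seed)
    tp = rng.binomial(n_positive, metrics_a.sensitivity, size=reps).astype(float)
    fp = rng.binomial(n_negative, 1.0 - metrics_a.specificity, size=reps).astype(float)
    tn = n_negative - fp
    rep_metrics = {
        "sensitivity": tp / n_positive,
        "specificity": tn / n_negative,
        "accuracy": (tp + tn) / (n_positive + n_negative),
        "ppv": np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan),
    }
    obs_b = metrics_b.as_dict()
    p_values, excluded = {}, {}
    for metric, direction in directions.items():
        rep = rep_metrics[metric]
        valid = ~np.isnan(rep)
        excluded[metric] = int((~valid).sum())
        observed = obs_b[metric]
        if np.isnan(observed):
            p_values[metric] = float("nan")
            continue
        if direction == "greater":
            count = int((rep[valid] >= observed).sum())
        elif direction == "less":
            count = int((rep[valid] <= observed).sum())
        else:
            raise ValueError(f"direction must be greater/less, got {direction!r}")
        n_valid = int(valid.sum())
        p_values[metric] = (1 + count) / (n_valid + 1)
    return PerfTestResult(p_values=p_values, reps=reps, directions=directions,
                          excluded=excluded)


def baseline_rate_test(flagged_count: int, hit_count: int, baseline_rate: float) -> float:
    """One-sided exact binomial tail for enrichment over a baseline rate.

    Probability of observing at least ``hit_count`` progressors among
    ``flagged_count`` flagged participants when each progresses
    independently at ``baseline_rate``.
    """
    if not 0 <= baseline_rate <= 1:
        raise ValueError("baseline rate must lie in [0, 1]")
    if hit_count > flagged_count:
        raise ValueError("hit count cannot exceed flagged count")
    return float(stats.binom.sf(hit_count - 1, flagged_count, baseline_rate))


# ---------------------------------------------------------------------------
# ROC comparison against standard algorithms

def _comparison_estimators(seed: int) -> dict:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    # documented default hyperparameters; adjust via config if needed
    return {
        "rbf_svm": SVC(kernel="rbf", class_weight="balanced"),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "gaussian_nb": GaussianNB(),
        "linear_svm": SVC(kernel="linear", class_weight="balanced"),
    }


def _scores(est, X: np.ndarray, pos_index: int) -> np.ndarray:
    if hasattr(est, "decision_function"):
        s = est.decision_function(X)
        return s if pos_index == 1 else -s
    return est.predict_proba(X)[:, pos_index]


def roc_points(truth: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """False-positive-rate / true-positive-rate curve points."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(truth, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(np.asarray(tpr)[order], np.asarray(fpr)[order]))


def compare_classifiers(train: pd.DataFrame, test: pd.DataFrame,
                        config, pos_label: str = "AD",
                        test_pos_label: str | None = None,
                        fit_two_stage: bool = True) -> tuple[pd.DataFrame, dict]:
    """ROC curves and AUCs for standard classifiers plus the two-stage model.

    Models are trained on the (standardized) training table and scored on
    the test table; the test positive class may differ from the training one
    (dementia-trained rules scored on progressor detection).  Returns an AUC
    table with each model's operating point, and the per-model ROC curves.
    """
    from .hps import Standardizer, fit_hps

    test_pos_label = test_pos_label or pos_label
    truth = (test["diagnosis"] == test_pos_label).to_numpy()
    if truth.all() or not truth.any():
        raise ValueError("test set must contain both classes")
    std = Standardizer.fit(train, config.columns)
    Xtr, Xte = std.transform(train), std.transform(test)
    ytr = train["diagnosis"].to_numpy()

    curves, rows = {}, []
    for name, est in _comparison_estimators(config.seed).items():
        est.fit(Xtr, ytr)
        pos_index = int(np.flatnonzero(est.classes_ == pos_label)[0])
        s = _scores(est, Xte, pos_index)
        pts = roc_points(truth, s)
        pred_pos = est.predict(Xte) == pos_label
        rows.append({"model": name,
                     "auc": trapezoid_auc(pts["fpr"], pts["tpr"]),
                     "op_fpr": float((pred_pos & ~truth).sum() / (~truth).sum()),
                     "op_tpr": float((pred_pos & truth).sum() / truth.sum())})
        curves[name] = pts
    if fit_two_stage:
        model = fit_hps(train, config, pos_label=pos_label)
        frame = model.decision_frame(test)
        s = frame["stage2_probability"].to_numpy()
        pts = roc_points(truth, s)
        flagged = (frame["risk_class"] == "high_confidence").to_numpy()
        rows.append({"model": "hps",
                     "auc": trapezoid_auc(pts["fpr"], pts["tpr"]),
                     "op_fpr": float((flagged & ~truth).sum() / (~truth).sum()),
                     "op_tpr": float((flagged & truth).sum() / truth.sum())})
        curves["hps"] = pts
    return pd.DataFrame(rows), curves
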