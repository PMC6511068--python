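"""Two-stage highly-predictive-signature (HPS) classifier.

The goal is a *high-specificity* prognostic rule: flag only participants
whose dementia-like profile is so robust that a prediction of progression is
almost always correct, accepting that many true progressors go unflagged.

Stage 1 perturbs a linear support-vector machine by training it on many
random class-stratified subsamples of the AD-vs-CN training set and scoring
each participant only on replications where they were held out.  The *hit
probability* is the fraction of those held-out appearances in which the
participant was classified correctly.  Dementia patients with a perfect hit
record (hit probability 1.0 by default) are "high-confidence" cases.

Stage 2 fits an L1-regularized logistic regression on the full training
sample to predict high-confidence status from the same features; the sparse
coefficient vector is the *signature*.  Applied to mild-cognitive-impairment
(MCI) patients, stage-2 positives are flagged "high confidence" (predicted
progressors), stage-1-only positives "low confidence", the rest "negative".

The ensemble size and subsample fraction are tuned on a validation MCI
cohort for maximum positive predictive value and specificity subject to a
minimum 30% sensitivity.

Randomness contract (needed for exact replay): the subsample for ensemble
replication ``r`` is drawn from ``numpy.random.default_rng([seed, r])`` by
taking, for each class in sorted label order, the first
``max(1, round(fraction * n_class))`` indices of an ``rng.permutation`` of
that class's row positions.  All scikit-learn splitters receive integer
seeds derived from the master seed via ``numpy.random.SeedSequence`` with
fixed per-component tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .features import feature_columns
from .evaluation import ConfusionCounts, confusion_metrics

DEFAULT_C_GRID = tuple(np.logspace(-2, 1, 15))
SUBSAMPLE_COUNTS = (100, 500, 1000)
SUBSAMPLE_FRACTIONS = (0.10, 0.20, 0.30, 0.50)

# fixed tags for deriving component seeds from the master seed
_SEED_TAGS = {"stage1_grid": 11, "outer_cv": 12, "stage2_grid": 13}


def derive_seed(master: int, component: str) -> int:
    """Stable integer sub-seed for a named pipeline component (< 2^31)."""
    tag = _SEED_TAGS[component]
    return int(np.random.SeedSequence([int(master), tag]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class HPSConfig:
    """Tunable parameters of the two-stage procedure.

    Grid defaults follow the standard recipe: C grids of 15 log-spaced
    values from 1e-2 to 1e1 for both stages; stage-1 model selection on a
    stratified shuffle split (50 splits, 20% test), stage-2 on a stratified
    shuffle split (500 splits, 50% test); ensemble of ``n_subsamples``
    class-stratified subsamples of the given fraction; a participant is
    high-confidence when their hit probability reaches ``hit_threshold``
    (1.0 = a perfect record) under the dementia label.
    """

    mode: str = "VCOG"
    n_subtypes: int = 7
    svm_C_grid: tuple = DEFAULT_C_GRID
    stage1_splits: int = 50
    stage1_test_size: float = 0.2
    n_subsamples: int = 500
    subsample_fraction: float = 0.5
    stage2_C_grid: tuple = DEFAULT_C_GRID
    stage2_splits: int = 500
    stage2_test_size: float = 0.5
    hit_threshold: float = 1.0
    stage2_threshold: float = 0.5
    outer_folds: int = 10
    seed: int = 0
    log_spaced_note: str = "C grids are log10-equally spaced"

    def __post_init__(self):
        if len(self.svm_C_grid) == 0 or len(self.stage2_C_grid) == 0:
            raise ValueError("C grids must be non-empty")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample fraction must lie in (0, 1)")
        if not 0 < self.hit_threshold <= 1:
            raise ValueError("hit threshold must lie in (0, 1]")

    @property
    def columns(self) -> list[str]:
        return feature_columns(self.mode, self.n_subtypes)


@dataclass
class Standardizer:
    """Per-feature z-scoring with training-sample mean and SD."""

    columns: list[str]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame, columns: list[str]) -> "Standardizer":
        X = table[columns].to_numpy(float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            bad = [c for c, z in zip(columns, zero) if z]
            raise ValueError(f"zero-variance feature(s): {bad}")
        return cls(list(columns), mean, sd)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks modelling features: {missing}")
        X = table[self.columns].to_numpy(float)
        if np.isnan(X).any():
            bad = [c for c in self.columns if table[c].isna().any()]
            raise ValueError(f"missing values in modelling features: {bad}")
        return (X - self.mean) / self.sd


@dataclass
class StageOneResult:
    """Ensemble summary: hit probabilities and the base SVM decision rule."""

    hit_probability: np.ndarray     # nan where never held out
    appearances: np.ndarray
    hits: np.ndarray
    C: float
    svm_coef: np.ndarray
    svm_intercept: float
    pos_sign: float                 # sign of the decision function on the positive side
    cv_metrics: dict = field(default_factory=dict)


def _mean_split_accuracy(est_factory, X, y, splitter) -> float:
    accs = []
    for tr, te in splitter.split(X, y):
        est = est_factory().fit(X[tr], y[tr])
        accs.append(float((est.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def _select_C(grid, est_factory, X, y, splitter_factory) -> tuple[float, pd.DataFrame]:
    rows = []
    for C in grid:
        acc = _mean_split_accuracy(lambda C=C: est_factory(C), X, y, splitter_factory())
        rows.append((float(C), acc))
    table = pd.DataFrame(rows, columns=["C", "mean_accuracy"])
    # ties go to the smaller C (the grid is stored in increasing order)
    best = table.loc[table["mean_accuracy"].idxmax()]
    return float(best["C"]), table


def _svm(C: float) -> SVC:
    return SVC(kernel="linear", C=C, class_weight="balanced")


def fit_base_svm(X: np.ndarray, y: np.ndarray, config: HPSConfig,
                 pos_label: str = "AD") -> StageOneResult:
    """Stage-1 base model: linear SVM with inverse-frequency class weights.

    C is chosen by mean accuracy over a stratified shuffle split
    (``stage1_splits`` splits, ``stage1_test_size`` test fraction), ties to
    the smaller C.  An outer stratified k-fold reports cross-validated
    accuracy/sensitivity/specificity/PPV, and the returned rule is refit on
    all rows with the selected C.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if len(y) < 10:
        raise ValueError("need at least 10 participants")
    grid_seed = derive_seed(config.seed, "stage1_grid")
    C, _ = _select_C(
        sorted(config.svm_C_grid), _svm, X, y,
        lambda: StratifiedShuffleSplit(n_splits=config.stage1_splits,
                                       test_size=config.stage1_test_size,
                                       random_state=grid_seed))
    # outer cross-validated performance report
    cv_seed = derive_seed(config.seed, "outer_cv")
    folds = StratifiedKFold(n_splits=config.outer_folds, shuffle=True, random_state=cv_seed)
    tp = fp = tn = fn = 0
    for tr, te in folds.split(X, y):
        pred = _svm(C).fit(X[tr], y[tr]).predict(X[te])
        truth = y[te]
        tp += int(((pred == pos_label) & (truth == pos_label)).sum())
        fp += int(((pred == pos_label) & (truth != pos_label)).sum())
        tn += int(((pred != pos_label) & (truth != pos_label)).sum())
        fn += int(((pred != pos_label) & (truth == pos_label)).sum())
    metrics = confusion_metrics(ConfusionCounts(tp, fp, tn, fn)).as_dict()
    final = _svm(C).fit(X, y)
    pos_sign = 1.0 if final.classes_[1] == pos_label else -1.0
    hp, app, hits = compute_hit_counts(X, y, C, config)
    return StageOneResult(hit_probability=hp, appearances=app, hits=hits, C=C,
                          svm_coef=final.coef_.ravel().copy(),
                          svm_intercept=float(final.intercept_[0]),
                          pos_sign=pos_sign, cv_metrics=metrics)


def draw_subsample(y: np.ndarray, fraction: float, seed: int, replication: int) -> np.ndarray:
    """Class-stratified subsample indices for one ensemble replication.

    Implements the documented randomness contract:
    ``rng = default_rng([seed, replication])``; for each class in sorted
    label order, permute that class's row positions and keep the first
    ``max(1, round(fraction * n_class))``.  Because at least one row per
    class is always retained, a subsample can never miss a class.
    """
    rng = np.random.default_rng([int(seed), int(replication)])
    keep = []
    for cls in np.unique(y):                      # np.unique sorts labels
        idx = np.flatnonzero(y == cls)
        m = max(1, int(round(fraction * len(idx))))
        keep.append(idx[rng.permutation(len(idx))[:m]])
    return np.sort(np.concatenate(keep))


def compute_hit_counts(X: np.ndarray, y: np.ndarray, C: float, config: HPSConfig
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subsampling ensemble: hit probability per participant.

    For each of ``n_subsamples`` replications, an SVM (fixed C selected on
    the full sample, inverse-frequency class weights) is trained on a
    class-stratified subsample and predicts the held-out complement; a
    participant's hit probability is their correct-prediction count divided
    by the number of replications in which they were held out.  Participants
    never held out get NaN (flagged undefined).
    """
    n = len(y)
    hits = np.zeros(n)
    appearances = np.zeros(n)
    for r in range(config.n_subsamples):
        train_idx = draw_subsample(y, config.subsample_fraction, config.seed, r)
        test_mask = np.ones(n, dtype=bool)
        test_mask[train_idx] = False
        if not test_mask.any():
            continue
        est = _svm(C).fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_mask])
        appearances[test_mask] += 1
        hits[test_mask] += (pred == y[test_mask])
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(appearances > 0, hits / np.maximum(appearances, 1), np.nan)
    return hp, appearances, hits


def label_high_confidence(stage1: StageOneResult, y: np.ndarray,
                          pos_label: str = "AD", hit_threshold: float = 1.0
                          ) -> np.ndarray:
    """High-confidence cases: dementia label, perfect (>= threshold) hit record."""
    y = np.asarray(y)
    hp = stage1.hit_probability
    with np.errstate(invalid="ignore"):
        ok = (stage1.appearances > 0) & (np.nan_to_num(hp, nan=-1.0) >= hit_threshold)
    return (y == pos_label) & ok


@dataclass
class StageTwoResult:
    coef: np.ndarray
    intercept: float
    C: float
    grid_table: pd.DataFrame | None = None


def _logistic(C: float) -> LogisticRegression:
    # lasso-penalized logistic regression (l1_ratio=1 is the pure L1 penalty);
    # liblinear shuffles coordinates internally, so pin its seed for
    # bit-reproducible fits
    return LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear", random_state=0)


def fit_stage_two(X: np.ndarray, hc_mask: np.ndarray, config: HPSConfig) -> StageTwoResult:
    """L1 logistic signature predicting high-confidence status.

    C is chosen by mean accuracy over a stratified shuffle split
    (``stage2_splits`` splits, ``stage2_test_size`` test fraction); ties go
    to the smaller C, i.e. the sparser model.  The final fit uses all rows.
    Coefficients are on standardized features and read as pseudo z-scores.
    """
    hc_mask = np.asarray(hc_mask, dtype=bool)
    if hc_mask.all() or not hc_mask.any():
        raise ValueError("high-confidence mask must contain both classes")
    grid_seed = derive_seed(config.seed, "stage2_grid")
    C, table = _select_C(
        sorted(config.stage2_C_grid), _logistic, X, hc_mask,
        lambda: StratifiedShuffleSplit(n_splits=config.stage2_splits,
                                       test_size=config.stage2_test_size,
                                       random_state=grid_seed))
    final = _logistic(C).fit(X, hc_mask)
    # classes_ for a boolean target are [False, True]: decision > 0 => P(hc) > .5
    return StageTwoResult(coef=final.coef_.ravel().copy(),
                          intercept=float(final.intercept_[0]), C=C, grid_table=table)


@dataclass
class HPSModel:
    """Fitted two-stage model, serializable to human-readable JSON."""

    config: HPSConfig
    standardizer: Standardizer
    stage1: StageOneResult
    hc_mask: np.ndarray
    stage2: StageTwoResult
    pos_label: str = "AD"

    # ---- prediction -------------------------------------------------------
    def decision_frame(self, table: pd.DataFrame) -> pd.DataFrame:
        """Stage-1 hit flag, stage-2 probability, and risk class per row.

        Risk class: ``high_confidence`` when the stage-2 probability reaches
        the threshold, else ``low_confidence`` when the full-sample SVM
        predicts the dementia class, else ``negative``.
        """
        Z = self.standardizer.transform(table)
        svm_score = self.stage1.pos_sign * (Z @ self.stage1.svm_coef + self.stage1.svm_intercept)
        stage1_hit = svm_score > 0
        logit = Z @ self.stage2.coef + self.stage2.intercept
        prob = 1.0 / (1.0 + np.exp(-logit))
        cls = np.where(prob >= self.config.stage2_threshold, "high_confidence",
                       np.where(stage1_hit, "low_confidence", "negative"))
        out = pd.DataFrame({
            "stage1_hit": stage1_hit,
            "stage1_score": svm_score,
            "stage2_probability": prob,
            "risk_class": cls,
        })
        if "participant_id" in table.columns:
            out.insert(0, "participant_id", table["participant_id"].to_numpy())
        return out

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Three-way risk class per participant."""
        return self.decision_frame(table)["risk_class"]

    # ---- serialization ----------------------------------------------------
    def to_json(self, path: str) -> None:
        cfg = asdict(self.config)
        cfg["svm_C_grid"] = [float(c) for c in cfg["svm_C_grid"]]
        cfg["stage2_C_grid"] = [float(c) for c in cfg["stage2_C_grid"]]
        payload = {
            "config": cfg,
            "pos_label": self.pos_label,
            "standardizer": {"columns": self.standardizer.columns,
                             "mean": self.standardizer.mean.tolist(),
                             "sd": self.standardizer.sd.tolist()},
            "stage1": {"C": self.stage1.C,
                       "svm_coef": self.stage1.svm_coef.tolist(),
                       "svm_intercept": self.stage1.svm_intercept,
                       "pos_sign": self.stage1.pos_sign,
                       "hit_probability": np.where(
                           np.isnan(self.stage1.hit_probability), None,
                           self.stage1.hit_probability).tolist(),
                       "appearances": self.stage1.appearances.tolist(),
                       "cv_metrics": self.stage1.cv_metrics},
            "hc_mask": [bool(b) for b in self.hc_mask],
            "stage2": {"C": self.stage2.C, "coef": self.stage2.coef.tolist(),
                       "intercept": self.stage2.intercept},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "HPSModel":
        with open(path) as fh:
            d = json.load(fh)
        cfg = dict(d["config"])
        cfg["svm_C_grid"] = tuple(cfg["svm_C_grid"])
        cfg["stage2_C_grid"] = tuple(cfg["stage2_C_grid"])
        config = HPSConfig(**cfg)
        std = Standardizer(d["standardizer"]["columns"],
                           np.array(d["standardizer"]["mean"]),
                           np.array(d["standardizer"]["sd"]))
        hp = np.array([np.nan if v is None else v for v in d["stage1"]["hit_probability"]])
        st1 = StageOneResult(hit_probability=hp,
                             appearances=np.array(d["stage1"]["appearances"]),
                             hits=np.round(hp * np.array(d["stage1"]["appearances"])),
                             C=d["stage1"]["C"],
                             svm_coef=np.array(d["stage1"]["svm_coef"]),
                             svm_intercept=d["stage1"]["svm_intercept"],
                             pos_sign=d["stage1"]["pos_sign"],
                             cv_metrics=d["stage1"]["cv_metrics"])
        st2 = StageTwoResult(coef=np.array(d["stage2"]["coef"]),
                             intercept=d["stage2"]["intercept"], C=d["stage2"]["C"])
        return cls(config=config, standardizer=std, stage1=st1,
                   hc_mask=np.array(d["hc_mask"], dtype=bool), stage2=st2,
                   pos_label=d["pos_label"])


def fit_hps(train: pd.DataFrame, config: HPSConfig, pos_label: str = "AD") -> HPSModel:
    """Fit the full two-stage model on a training table (CN + AD rows)."""
    std = Standardizer.fit(train, config.columns)
    X = std.transform(train)
    y = train["diagnosis"].to_numpy()
    stage1 = fit_base_svm(X, y, config, pos_label=pos_label)
    hc = label_high_confidence(stage1, y, pos_label=pos_label,
                               hit_threshold=config.hit_threshold)
    stage2 = fit_stage_two(X, hc, config)
    return HPSModel(config=config, standardizer=std, stage1=stage1,
                    hc_mask=hc, stage2=stage2, pos_label=pos_label)


def _mci_detection_metrics(model: HPSModel, validation: pd.DataFrame):
    """Confusion metrics for high-confidence detection of progressors."""
    frame = model.decision_frame(validation)
    flagged = (frame["risk_class"] == "high_confidence").to_numpy()
    truth = (validation["diagnosis"] == "pMCI").to_numpy()
    counts = ConfusionCounts(int((flagged & truth).sum()), int((flagged & ~truth).sum()),
                             int((~flagged & ~truth).sum()), int((~flagged & truth).sum()))
    return confusion_metrics(counts), counts


def tune_subsampling(train: pd.DataFrame, validation_mci: pd.DataFrame,
                     config: HPSConfig,
                     counts: tuple = SUBSAMPLE_COUNTS,
                     fractions: tuple = SUBSAMPLE_FRACTIONS,
                     min_sensitivity: float = 0.30
                     ) -> tuple[tuple[int, float], pd.DataFrame]:
    """Choose ensemble size and subsample fraction on the validation cohort.

    For every (count, fraction) cell the full two-stage model is refit on
    the AD-vs-CN training table and evaluated on high-confidence detection
    of progressors among the validation MCI participants.  Cells below the
    sensitivity floor (default 30%) are discarded; survivors are ranked
    lexicographically by (PPV, specificity), ties resolved toward fewer
    subsamples then a larger fraction.  When no cell clears the floor the
    best-PPV cell is returned flagged ``constraint_met = False``.
    Returns the winning (count, fraction) and the full audit table.
    """
    diag = set(validation_mci["diagnosis"])
    if "sMCI" not in diag or "pMCI" not in diag:
        raise ValueError("validation cohort must contain both sMCI and pMCI")
    from dataclasses import replace

    rows = []
    for n_sub in counts:
        for frac in fractions:
            cfg = replace(config, n_subsamples=int(n_sub), subsample_fraction=float(frac))
            model = fit_hps(train, cfg)
            metrics, cc = _mci_detection_metrics(model, validation_mci)
            rows.append({"n_subsamples": int(n_sub), "fraction": float(frac),
                         "sensitivity": metrics.sensitivity,
                         "specificity": metrics.specificity,
                         "ppv": metrics.ppv, "accuracy": metrics.accuracy,
                         "tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn})
    table = pd.DataFrame(rows)

    def rank_key(row):
        # ties: fewer subsamples, then larger fraction
        return (np.nan_to_num(row["ppv"], nan=-1.0),
                np.nan_to_num(row["specificity"], nan=-1.0),
                -row["n_subsamples"], row["fraction"])

    eligible = table[table["sensitivity"].fillna(0) >= min_sensitivity]
    pool = eligible if len(eligible) else table
    best = max(pool.to_dict("records"), key=rank_key)
    table["constraint_met"] = table["sensitivity"].fillna(0) >= min_sensitivity
    table["selected"] = [(r["n_subsamples"] == best["n_subsamples"])
                         and (r["fraction"] == best["fraction"])
                         for r in table.to_dict("records")]
    return (int(best["n_subsamples"]), float(best["fraction"])), table
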