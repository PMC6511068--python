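"""Pipeline orchestration: feature assembly, end-to-end runs, provenance.

The canonical workflow mirrors the train/validate/test design the method
was built for: dementia and control participants of the first cohort train
the two-stage signature, that cohort's MCI patients tune the subsampling
ensemble, and a second, independent MCI cohort measures final performance.
Cohort roles are explicit ``cohort`` tags in the feature table (``train`` /
``validation`` / ``test``), never inferred from file names.

Every run writes a manifest (config snapshot, package version, derived
seeds, input checksums, stage timings) sufficient to re-execute the run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (ConfusionCounts, DEFAULT_PREVALENCE, baseline_rate_test,
                         confusion_metrics, performance_difference_test)
from .enrichment import assign_risk_groups, enrichment_table
from .features import feature_columns, validate_feature_table
from .hps import HPSConfig, fit_hps, tune_subsampling
from .subtyping import VoxelMapSet, compute_weights, fit_subtypes
from .synthetic import default_cohort_spec, simulate_cohort


@dataclass
class RunConfig:
    """Everything one pipeline run needs.  Paths may be None to simulate."""

    out_dir: str
    features_path: str | None = None
    maps_path: str | None = None
    confounds_path: str | None = None
    mode: str = "VCOG"
    n_subtypes: int = 7
    hps: HPSConfig = field(default_factory=HPSConfig)
    tune: bool = False
    prevalence: float = DEFAULT_PREVALENCE
    mc_reps: int = 100_000
    seed: int = 0
    sim_scale: float = 1.0


def assemble_features(base: pd.DataFrame, weights: pd.DataFrame | None,
                      mode: str, n_subtypes: int = 7
                      ) -> tuple[pd.DataFrame, list]:
    """Join demographics/cognition with subtype weights; drop incomplete rows.

    ``weights`` (optional) is indexed by participant id with columns
    ``vbm_1..vbm_k`` (the subtyping stage's output).  Rows missing any
    modelling feature for the chosen mode are dropped and their ids
    returned.  Duplicate ids are rejected; a join that loses more than half
    the rows triggers a loud warning.
    """
    if base["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids in feature table")
    table = base.copy()
    if weights is not None:
        if weights.index.duplicated().any():
            raise ValueError("duplicate participant ids in weights")
        table = table.drop(columns=[c for c in weights.columns if c in table.columns])
        table = table.join(weights, on="participant_id", how="inner")
        if len(table) < 0.5 * len(base):
            warnings.warn(
                f"joining weights kept only {len(table)}/{len(base)} rows — "
                "check that participant ids match")
    cols = feature_columns(mode, n_subtypes)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"assembled table lacks modelling columns: {missing_cols}")
    complete = table[cols].notna().all(axis=1)
    dropped = table.loc[~complete, "participant_id"].tolist()
    return table[complete].reset_index(drop=True), dropped


def tag_simulated_cohorts(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign train/validation/test roles to a simulated cohort.

    CN and AD rows train the signature; MCI rows are split in half at
    random (per diagnosis, seeded) into validation and test cohorts.
    """
    rng = np.random.default_rng([int(seed), 97])
    table = table.copy()
    cohort = np.where(table["diagnosis"].isin(["CN", "AD"]), "train", "").astype(object)
    for diag in ("sMCI", "pMCI"):
        idx = np.flatnonzero(table["diagnosis"].to_numpy() == diag)
        half = rng.permutation(len(idx))
        cohort_idx = idx[half]
        cohort[cohort_idx[: len(idx) // 2]] = "validation"
        cohort[cohort_idx[len(idx) // 2:]] = "test"
    table["cohort"] = cohort
    return table


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _mci_counts(flagged: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(int((flagged & truth).sum()), int((flagged & ~truth).sum()),
                           int((~flagged & ~truth).sum()), int((~flagged & truth).sum()))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts.

    Stages: input (load or simulate) -> optional subtype fit + weight
    projection -> feature assembly -> subsampling tuning (optional) ->
    final two-stage fit -> prediction on the test cohort -> evaluation
    (raw and prevalence-adjusted metrics, Monte-Carlo comparison against
    the base SVM, enrichment over the baseline rate) -> trait enrichment.
    Returns the manifest dict; artifacts land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "config": _config_dict(config),
                      "timings": {}, "inputs": {}, "stages": {}}
    t0 = time.time()

    def _stage(name):
        manifest["timings"][name] = round(time.time() - t0, 3)

    # ---- inputs -----------------------------------------------------------
    if config.features_path:
        table = pd.read_csv(config.features_path)
        manifest["inputs"]["features"] = {"path": config.features_path,
                                          "sha256": _sha256(config.features_path)}
    else:
        spec = default_cohort_spec(scale=config.sim_scale)
        table = simulate_cohort(spec, seed=config.seed)
        table = tag_simulated_cohorts(table, config.seed)
        manifest["inputs"]["features"] = {"simulated": True, "seed": config.seed,
                                          "scale": config.sim_scale,
                                          "n": int(len(table))}
    if "cohort" not in table.columns:
        raise ValueError("feature table needs a 'cohort' column (train/validation/test)")
    _stage("input")

    # ---- optional subtyping on provided maps ------------------------------
    weights = None
    if config.maps_path:
        if config.mode.upper() == "COG":
            raise ValueError("maps supplied but mode COG uses no subtype weights")
        maps_df = pd.read_csv(config.maps_path, index_col=0)
        confounds = (pd.read_csv(config.confounds_path)
                     if config.confounds_path else table)
        confounds = confounds.set_index("participant_id").loc[maps_df.index].reset_index()
        maps = VoxelMapSet(maps_df.to_numpy(float), maps_df.index.to_numpy())
        train_ids = set(table.loc[table["cohort"] == "train", "participant_id"])
        tr_mask = np.array([i in train_ids for i in maps.ids])
        model = fit_subtypes(
            VoxelMapSet(maps.values[tr_mask], maps.ids[tr_mask]),
            confounds[tr_mask].reset_index(drop=True), k=config.n_subtypes)
        weights = compute_weights(model, maps, confounds)
        manifest["stages"]["subtyping"] = {"k": config.n_subtypes,
                                           "n_train_maps": int(tr_mask.sum())}
    _stage("subtyping")

    # ---- feature assembly -------------------------------------------------
    table, dropped = assemble_features(table, weights, config.mode, config.n_subtypes)
    validate_feature_table(table, config.mode, config.n_subtypes)
    manifest["stages"]["assembly"] = {"n_rows": int(len(table)),
                                      "dropped_ids": [str(d) for d in dropped]}
    train = table[table["cohort"] == "train"].reset_index(drop=True)
    validation = table[table["cohort"] == "validation"].reset_index(drop=True)
    test = table[table["cohort"] == "test"].reset_index(drop=True)
    if train.empty or test.empty:
        raise ValueError("need non-empty train and test cohorts")
    table.to_csv(out / "cohort.csv", index=False)
    _stage("assembly")

    # ---- tuning -----------------------------------------------------------
    hps_cfg = replace(config.hps, mode=config.mode, n_subtypes=config.n_subtypes,
                      seed=config.seed)
    if config.tune:
        if validation.empty:
            raise ValueError("tuning requested but the validation cohort is empty")
        (n_sub, frac), tuning = tune_subsampling(train, validation, hps_cfg)
        hps_cfg = replace(hps_cfg, n_subsamples=n_sub, subsample_fraction=frac)
        tuning.to_csv(out / "tuning.csv", index=False)
        manifest["stages"]["tuning"] = {"n_subsamples": n_sub, "fraction": frac}
    _stage("tuning")

    # ---- final fit + prediction -------------------------------------------
    model = fit_hps(train, hps_cfg)
    model.to_json(str(out / "model.json"))
    frame = model.decision_frame(test)
    classes = frame.copy()
    classes.insert(1, "diagnosis", test["diagnosis"].to_numpy())
    classes.to_csv(out / "classes.csv", index=False)
    manifest["stages"]["hps"] = {"svm_C": model.stage1.C, "logistic_C": model.stage2.C,
                                 "n_high_confidence_train": int(model.hc_mask.sum())}
    _stage("fit_predict")

    # ---- evaluation -------------------------------------------------------
    truth = (test["diagnosis"] == "pMCI").to_numpy()
    flagged_hps = (frame["risk_class"] == "high_confidence").to_numpy()
    flagged_svm = frame["stage1_hit"].to_numpy()
    rows = []
    comparisons = {}
    if truth.any() and (~truth).any():
        m_hps = confusion_metrics(_mci_counts(flagged_hps, truth), config.prevalence)
        m_svm = confusion_metrics(_mci_counts(flagged_svm, truth), config.prevalence)
        rows.append({"model": "hps", **m_hps.as_dict()})
        rows.append({"model": "linear_svm", **m_svm.as_dict()})
        perf = performance_difference_test(
            m_svm, m_hps, n_positive=int(truth.sum()), n_negative=int((~truth).sum()),
            reps=config.mc_reps, seed=config.seed)
        comparisons["svm_vs_hps_p"] = perf.p_values
        if flagged_hps.any():
            comparisons["enrichment_over_baseline_p"] = baseline_rate_test(
                int(flagged_hps.sum()), int((flagged_hps & truth).sum()),
                float(truth.mean()))
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    manifest["stages"]["evaluation"] = comparisons
    _stage("evaluation")

    # ---- enrichment -------------------------------------------------------
    risk = assign_risk_groups(flagged_svm, flagged_hps)
    if flagged_hps.any():
        enr = enrichment_table(test, risk, reps=config.mc_reps, seed=config.seed)
        enr.to_csv(out / "enrichment.csv", index=False)
        manifest["stages"]["enrichment"] = {
            r["trait"]: r["p_value"] for r in enr.to_dict("records")}
    _stage("enrichment")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["hps"]["svm_C_grid"] = [float(c) for c in d["hps"]["svm_C_grid"]]
    d["hps"]["stage2_C_grid"] = [float(c) for c in d["hps"]["stage2_C_grid"]]
    return d
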