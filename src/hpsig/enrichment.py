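"""Characterization of the flagged MCI subgroup.

Partitions an MCI cohort into three risk groups (high confidence / low
confidence / negative), calls CSF biomarker positivity at standard cut-offs
(amyloid-beta 1-42 positive below 192 pg/mL, total tau positive above
93 pg/mL), and tests whether the high-confidence subgroup is enriched for a
binary trait (progression, APOE4 carriage, female sex, amyloid or tau
positivity) against a Monte-Carlo null of equally sized random subgroups
drawn without replacement from the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SUBCLASSES


@dataclass
class CSFThresholds:
    abeta_cutoff: float = 192.0     # pg/mL, positive strictly below
    tau_cutoff: float = 93.0        # pg/mL, positive strictly above

    def __post_init__(self):
        if self.abeta_cutoff <= 0 or self.tau_cutoff <= 0:
            raise ValueError("CSF cut-offs must be positive")


@dataclass
class EnrichmentResult:
    trait: str
    observed_proportion: float
    group_size: int
    reps: int
    p_value: float
    dropped_missing: int = 0


def assign_risk_groups(stage1_hits: np.ndarray, hps_hits: np.ndarray) -> pd.Series:
    """Three-way risk classes from the two classifiers' hit masks.

    high confidence = flagged by the two-stage signature; low confidence =
    flagged by the base SVM only; negative = flagged by neither.  The three
    classes partition the cohort.  A signature hit without a base-SVM hit is
    allowed (independent thresholds) but counted in ``.attrs``.
    """
    stage1_hits = np.asarray(stage1_hits, dtype=bool)
    hps_hits = np.asarray(hps_hits, dtype=bool)
    if stage1_hits.shape != hps_hits.shape:
        raise ValueError("masks must be aligned")
    cls = np.where(hps_hits, "high_confidence",
                   np.where(stage1_hits, "low_confidence", "negative"))
    out = pd.Series(pd.Categorical(cls, categories=list(SUBCLASSES)), name="risk_class")
    out.attrs["hps_without_stage1"] = int((hps_hits & ~stage1_hits).sum())
    return out


def csf_positivity(abeta, tau, thresholds: CSFThresholds | None = None
                   ) -> pd.DataFrame:
    """Amyloid/tau positivity calls; strict inequalities, missing propagates."""
    thresholds = thresholds or CSFThresholds()
    abeta = pd.Series(abeta, dtype=float)
    tau = pd.Series(tau, dtype=float)
    if (abeta.dropna() < 0).any() or (tau.dropna() < 0).any():
        raise ValueError("CSF concentrations cannot be negative")
    return pd.DataFrame({
        "abeta_positive": (abeta < thresholds.abeta_cutoff).mask(abeta.isna()),
        "tau_positive": (tau > thresholds.tau_cutoff).mask(tau.isna()),
    })


def enrichment_test(group_mask, trait_mask, reps: int = 100_000,
                    seed: int = 0, trait: str = "trait") -> EnrichmentResult:
    """Monte-Carlo enrichment of a trait in a subgroup.

    The null draws ``reps`` random subgroups of the same size from the
    cohort without replacement and records the trait proportion in each.
    One-sided p for enrichment:
    ``(1 + #{null proportion >= observed}) / (reps + 1)``.
    Rows with a missing trait are dropped from both the subgroup and the
    null pool; the dropped count is reported.
    """
    group_mask = pd.Series(group_mask).astype(bool).to_numpy()
    trait_values = pd.Series(trait_mask)
    missing = trait_values.isna().to_numpy()
    dropped = int(missing.sum())
    keep = ~missing
    g = group_mask[keep]
    t = trait_values[keep].astype(bool).to_numpy()
    size = int(g.sum())
    if size < 1:
        raise ValueError("subgroup is empty (after dropping missing-trait rows)")
    if size > len(t):
        raise ValueError("subgroup larger than the cohort pool")
    observed = float(t[g].mean())
    rng = np.random.default_rng(seed)
    count = 0
    # vectorized batches of permutation draws without replacement
    batch = max(1, min(reps, 20_000_000 // max(len(t), 1)))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        idx = np.argpartition(rng.random((b, len(t))), size - 1, axis=1)[:, :size]
        null_props = t[idx].mean(axis=1)
        count += int((null_props >= observed - 1e-12).sum())
        done += b
    p = (1 + count) / (reps + 1)
    return EnrichmentResult(trait=trait, observed_proportion=observed,
                            group_size=size, reps=reps, p_value=p,
                            dropped_missing=dropped)


def enrichment_table(features: pd.DataFrame, risk_class: pd.Series,
                     traits: dict[str, pd.Series] | None = None,
                     reps: int = 100_000, seed: int = 0,
                     group: str = "high_confidence") -> pd.DataFrame:
    """Run the enrichment test for several traits against one risk group.

    Default traits, taken from feature-table columns when present:
    progression (diagnosis == pMCI), APOE4 carriage, female sex, and CSF
    amyloid/tau positivity.  Raw one-sided p-values are reported; apply a
    multiplicity correction downstream if required.
    """
    if traits is None:
        traits = {}
        traits["progression"] = features["diagnosis"].eq("pMCI")
        if "apoe4" in features.columns:
            traits["apoe4"] = features["apoe4"]
        traits["female"] = features["sex"].eq(1)
        if "abeta" in features.columns or "tau" in features.columns:
            calls = csf_positivity(features.get("abeta", np.nan),
                                   features.get("tau", np.nan))
            traits["abeta_positive"] = calls["abeta_positive"]
            traits["tau_positive"] = calls["tau_positive"]
    mask = np.asarray(risk_class == group, dtype=bool)
    rows = []
    for i, (name, values) in enumerate(traits.items()):
        res = enrichment_test(mask, values, reps=reps,
                              seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                                       & 0x7FFFFFFF),
                              trait=name)
        rows.append({"trait": res.trait, "observed_proportion": res.observed_proportion,
                     "group_size": res.group_size, "reps": res.reps,
                     "p_value": res.p_value, "dropped_missing": res.dropped_missing})
    return pd.DataFrame(rows)
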