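"""Feature-table conventions shared across the pipeline.

A feature table is a pandas DataFrame with one row per participant.
Documented columns (the data dictionary shipped in ``docs/``):

====================  =======================================================
column                meaning
====================  =======================================================
participant_id        unique identifier (string or int)
cohort                role tag: ``train`` / ``validation`` / ``test``
diagnosis             clinical label: ``CN``, ``sMCI``, ``pMCI``, ``AD``
age                   years
sex                   binary, 1 = female
mean_gmv              mean modulated grey-matter density
tiv                   total intracranial volume (cm^3)
adas13                ADAS-Cog 13-item total (higher = worse)
mem                   composite memory score (ADNI-MEM style, z-scale)
exec                  composite executive score (ADNI-EF style, z-scale)
bnt                   Boston Naming Test total
clock                 clock-drawing score
vbm_1 .. vbm_k        atrophy-subtype weights (spatial correlations)
abeta                 optional CSF amyloid-beta 1-42 (pg/mL)
tau                   optional CSF total tau (pg/mL)
apoe4                 optional APOE epsilon-4 carrier flag (0/1)
subclass              optional simulator ground-truth risk subclass
====================  =======================================================

Modelling feature sets are selected by *mode*: ``VBM`` uses demographics +
subtype weights, ``COG`` demographics + cognition, ``VCOG`` everything.
Demographic covariates (age, sex, mean GMV, TIV) are included as features in
every mode.
"""

from __future__ import annotations

import pandas as pd

DIAGNOSES = ("CN", "sMCI", "pMCI", "AD")
SUBCLASSES = ("negative", "low_confidence", "high_confidence")

DEMOGRAPHIC_FEATURES = ["age", "sex", "mean_gmv", "tiv"]
COGNITIVE_FEATURES = ["adas13", "mem", "exec", "bnt", "clock"]

MODES = ("VBM", "COG", "VCOG")


def subtype_columns(k: int) -> list[str]:
    """Column names for k subtype weights."""
    return [f"vbm_{i}" for i in range(1, k + 1)]


def feature_columns(mode: str, n_subtypes: int = 7) -> list[str]:
    """Modelling feature columns for a feature mode.

    Parameters
    ----------
    mode
        One of ``VBM``, ``COG``, ``VCOG`` (case-insensitive).
    n_subtypes
        Number of subtype-weight columns, default 7.
    """
    mode = mode.upper()
    if mode not in MODES:
        raise ValueError(f"unknown feature mode {mode!r}; expected one of {MODES}")
    cols = list(DEMOGRAPHIC_FEATURES)
    if mode in ("COG", "VCOG"):
        cols += COGNITIVE_FEATURES
    if mode in ("VBM", "VCOG"):
        cols += subtype_columns(n_subtypes)
    return cols


def validate_feature_table(table: pd.DataFrame, mode: str = "VCOG",
                           n_subtypes: int = 7) -> None:
    """Check ids, diagnosis levels, and completeness of modelling features."""
    if "participant_id" in table.columns and table["participant_id"].duplicated().any():
        dupes = table.loc[table["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicate participant ids: {sorted(set(dupes))[:5]}")
    if "diagnosis" in table.columns:
        bad = set(table["diagnosis"].dropna()) - set(DIAGNOSES)
        if bad:
            raise ValueError(f"unknown diagnosis levels: {sorted(bad)}")
    cols = feature_columns(mode, n_subtypes)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table lacks modelling columns: {missing_cols}")
    if table[cols].isna().any().any():
        bad = [c for c in cols if table[c].isna().any()]
        raise ValueError(f"missing values in modelling features: {bad}")
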