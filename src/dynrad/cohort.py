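"""Cohort tables and per-phase feature CSVs.

The feature CSV is long-format: one row per (patient, phase), columns
``patient_id, phase, <feature 1>, <feature 2>, ...``.  The cohort table
carries one row per patient with the outcome and clinical covariates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from dynrad.images import PHASES

__all__ = ["read_feature_csv", "write_feature_csv", "phase_matrices", "validate_cohort"]

_CATEGORICAL_LEVELS = {
    "response": {"OR", "NOR"},
    "sex": {"male", "female"},
    "site": {"left", "rectum", "right"},
    "cea": {"normal", "high"},
    "afp": {"normal", "high"},
}


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format per-phase feature table.

    Returns a DataFrame indexed by ``(patient_id, phase)`` with one
    column per feature, names preserved verbatim.

    Raises
    ------
    ValueError
        On duplicated (patient, phase) rows, non-numeric feature cells,
        or phase labels outside the canonical set.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    for col in ("patient_id", "phase"):
        if col not in df.columns:
            raise ValueError(f"feature CSV must have a {col!r} column")
    bad_phases = set(df["phase"]) - set(PHASES)
    if bad_phases:
        raise ValueError(f"unknown phase labels {sorted(bad_phases)}; expected {PHASES}")
    dup = df.duplicated(subset=["patient_id", "phase"])
    if dup.any():
        rows = df.loc[dup, ["patient_id", "phase"]].to_records(index=False).tolist()
        raise ValueError(f"duplicated (patient, phase) rows: {rows[:5]}")
    feats = [c for c in df.columns if c not in ("patient_id", "phase")]
    for c in feats:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any() and not df[c].isna().any():
            raise ValueError(f"non-numeric value in feature column {c!r}")
        df[c] = vals
    return df.set_index(["patient_id", "phase"])


def write_feature_csv(per_phase: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write per-phase matrices as one long-format CSV (full precision)."""
    rows = []
    for phase, mat in per_phase.items():
        block = mat.copy()
        block.insert(0, "phase", phase)
        block.insert(0, "patient_id", mat.index.astype(str))
        rows.append(block)
    out = pd.concat(rows, axis=0, ignore_index=True)
    # default float repr is shortest-round-trip: values survive bit-for-bit
    out.to_csv(path, index=False)


def phase_matrices(long_df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a long-format feature table into per-phase wide matrices.

    Phases come back in canonical order; every patient must be present
    in every phase that occurs.
    """
    present = [p for p in PHASES if p in long_df.index.get_level_values("phase")]
    if not present:
        raise ValueError("empty feature table: no phase rows")
    out = {}
    for phase in present:
        out[phase] = long_df.xs(phase, level="phase").sort_index()
    patients = set(out[present[0]].index)
    for phase, mat in out.items():
        if set(mat.index) != patients:
            missing = patients.symmetric_difference(mat.index)
            raise ValueError(f"phase {phase!r} patient set mismatch: {sorted(missing)[:5]}")
    return out


def validate_cohort(df: pd.DataFrame, require_response: bool = True) -> pd.DataFrame:
    """Validate a per-patient cohort/outcome table.

    Checks unique ``patient_id``, nonnegative ``pfs_days``, binary
    ``event`` and the closed categorical levels; returns the table
    indexed by patient_id.
    """
    df = df.copy()
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].astype(str)
        df = df.set_index("patient_id")
    if df.index.has_duplicates:
        raise ValueError("patient_id values are not unique")
    if len(df) == 0:
        raise ValueError("empty cohort")
    if require_response and "response" not in df.columns:
        raise ValueError("cohort table must have a 'response' column")
    for col, levels in _CATEGORICAL_LEVELS.items():
        if col in df.columns:
            bad = set(df[col].dropna()) - levels
            if bad:
                raise ValueError(f"column {col!r}: invalid levels {sorted(bad)}")
    if "pfs_days" in df.columns:
        if (pd.to_numeric(df["pfs_days"]) < 0).any():
            raise ValueError("pfs_days must be nonnegative")
    if "event" in df.columns:
        if not set(pd.to_numeric(df["event"]).astype(int)) <= {0, 1}:
            raise ValueError("event must be 0/1")
    return df
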