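"""Reading, writing and validating trial-level CSV tables.

The interchange format is a tidy CSV with one row per trial.  Required
logical columns: participant_id, group, block, number, correct, rt_ms;
optional: response_side, trial_index, mapping, distance.  A ColumnMap adapts
externally produced CSVs (arbitrary header names, alternative codings of
the correctness column) to this schema without touching the source file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DIGITS, distance

REQUIRED = ("participant_id", "group", "block", "number", "correct", "rt_ms")
OPTIONAL = ("response_side", "trial_index", "mapping", "distance")

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


@dataclass
class ColumnMap:
    """Mapping from logical column names to CSV header names.

    `columns` maps logical -> actual header (identity by default);
    `correct_recode` optionally maps raw cell values of the correctness
    column to booleans, e.g. {"T": True, "F": False}.
    """

    columns: dict[str, str] = field(default_factory=dict)
    correct_recode: dict[str, bool] | None = None

    def actual(self, logical: str) -> str:
        return self.columns.get(logical, logical)


class TrialTableError(ValueError):
    """A trial table violates the task-design schema."""


def _parse_correct(series: pd.Series, recode: dict | None) -> pd.Series:
    if recode is not None:
        mapped = series.astype(str).map({str(k): v for k, v in recode.items()})
        if mapped.isna().any():
            bad = series[mapped.isna()].unique()[:5]
            raise TrialTableError(f"unrecognised correctness codes: {list(bad)}")
        return mapped.astype(bool)
    if series.dtype == bool:
        return series
    as_str = series.astype(str).str.strip().str.lower()
    out = pd.Series(index=series.index, dtype=object)
    out[as_str.isin(_TRUE_STRINGS)] = True
    out[as_str.isin(_FALSE_STRINGS)] = False
    if out.isna().any():
        bad = series[out.isna()].unique()[:5]
        raise TrialTableError(
            f"cannot parse correctness values {list(bad)}; provide a "
            "ColumnMap with correct_recode"
        )
    return out.astype(bool)


def validate_trials(df: pd.DataFrame, strict_design: bool = False) -> pd.DataFrame:
    """Validate (and lightly normalise) a trial table.

    Always enforced: required columns present, digits in the stimulus set
    (a row presenting 5 is a hard error), blocks in {1, 2}, RTs positive or
    missing, distance consistent with |number - 5|.  With
    ``strict_design=True`` additionally enforces the full design: 240 trials
    per block, each digit exactly 30 times per block.
    """
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {missing}")
    df = df.copy()
    df["number"] = df["number"].astype(int)
    df["block"] = df["block"].astype(int)

    bad5 = df.index[df["number"] == 5]
    if len(bad5):
        raise TrialTableError(
            f"digit 5 present at row(s) {bad5[:5].tolist()}: the standard is "
            "never a stimulus"
        )
    bad_digit = df.index[~df["number"].isin(DIGITS)]
    if len(bad_digit):
        raise TrialTableError(
            f"invalid digit(s) at row(s) {bad_digit[:5].tolist()}: stimuli "
            f"must be in {DIGITS}"
        )
    bad_block = df.index[~df["block"].isin((1, 2))]
    if len(bad_block):
        raise TrialTableError(f"invalid block at row(s) {bad_block[:5].tolist()}")

    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    neg = df.index[df["rt_ms"].notna() & (df["rt_ms"] <= 0)]
    if len(neg):
        raise TrialTableError(f"non-positive RT at row(s) {neg[:5].tolist()}")

    if "distance" in df.columns:
        mism = df.index[df["distance"].astype(int) != distance(df["number"])]
        if len(mism):
            raise TrialTableError(
                f"distance inconsistent with |number - 5| at row(s) "
                f"{mism[:5].tolist()}"
            )
    else:
        df["distance"] = distance(df["number"])

    if strict_design:
        counts = df.groupby(["participant_id", "block", "number"]).size()
        wrong = counts[counts != 30]
        if len(wrong):
            raise TrialTableError(
                f"design violation: digit counts != 30 per block for "
                f"{wrong.index[:5].tolist()}"
            )
    return df


def read_trials(path, colmap: ColumnMap | None = None,
                strict_design: bool = False) -> pd.DataFrame:
    """Read and validate a trial CSV, applying an optional ColumnMap."""
    colmap = colmap or ColumnMap()
    raw = pd.read_csv(path)
    rename = {}
    for logical in REQUIRED + OPTIONAL:
        actual = colmap.actual(logical)
        if actual in raw.columns:
            rename[actual] = logical
        elif logical in REQUIRED:
            raise TrialTableError(
                f"column {actual!r} (logical {logical!r}) not found in {path}"
            )
    df = raw.rename(columns=rename)
    df["correct"] = _parse_correct(df["correct"], colmap.correct_recode)
    return validate_trials(df, strict_design=strict_design)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV; missing RTs become empty fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
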