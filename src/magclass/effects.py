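"""Per-participant quantification of numerical distance, size, ratio and
SNARC effects.

All effects are OLS slopes fitted to digit-level mean RTs (8 points per
participant).  Distance |d-5| and magnitude d are exactly orthogonal over the
digit set {1,2,3,4,6,7,8,9}, so the two slopes of the multiple regression
coincide with their simple-regression counterparts.  Sign conventions:
negative distance slope = typical distance effect; positive magnitude slope =
typical size effect; negative slope of the right-minus-left RT difference on
magnitude = typical SNARC effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DIGIT_ARR, DIGITS, DIST_ARR, ratio


def aggregate_digit_means(table: pd.DataFrame, min_cell: int = 5) -> pd.DataFrame:
    """Mean RT per digit per participant.

    Returns a tidy frame (participant_id, number, mean_rt, n_trials,
    low_n flag).  A participant missing a digit entirely is an error: an
    8-point regression cannot be fitted.
    """
    g = table.groupby(["participant_id", "number"])["rt_ms"]
    out = g.agg(mean_rt="mean", n_trials="size").reset_index()
    for pid, sub in out.groupby("participant_id"):
        missing = set(DIGITS) - set(sub["number"])
        if missing:
            raise ValueError(
                f"participant {pid!r} has no retained trials for digit(s) "
                f"{sorted(missing)}"
            )
    out["low_n"] = out["n_trials"] < min_cell
    return out


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with intercept; returns (coefs, r_squared)."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    ss_res = np.sum((y - fitted) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return coef, float(r2)


def fit_distance_size(means_8: np.ndarray) -> dict:
    """Multiple OLS of the 8 digit means on distance and magnitude.

    `means_8` is ordered as design.DIGITS.  Returns intercept, the distance
    slope (nde_slope, ms/distance unit), the magnitude slope (nse_slope,
    ms/magnitude unit) and R^2.
    """
    y = np.asarray(means_8, dtype=float)
    if y.shape != (8,):
        raise ValueError("expected exactly 8 digit means ordered as DIGITS")
    if not np.all(np.isfinite(y)):
        raise ValueError("digit means must be finite")
    if np.ptp(y) == 0.0:
        return {"intercept": float(y[0]), "nde_slope": 0.0,
                "nse_slope": 0.0, "r_squared": 0.0}
    coef, r2 = _ols(y, np.column_stack([DIST_ARR, DIGIT_ARR]))
    return {"intercept": float(coef[0]), "nde_slope": float(coef[1]),
            "nse_slope": float(coef[2]), "r_squared": r2}


def fit_ratio(means_8: np.ndarray) -> float:
    """Simple OLS slope of the 8 digit means on the ratio min(d,5)/max(d,5)."""
    y = np.asarray(means_8, dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0
    coef, _ = _ols(y, ratio(DIGIT_ARR)[:, None])
    return float(coef[1])


def standardize_slopes(means_8: np.ndarray) -> dict:
    """Distance/size slopes after z-scoring means and predictors (unitless)."""
    y = np.asarray(means_8, dtype=float)
    if np.std(y, ddof=1) == 0.0:
        return {"nde_slope_std": 0.0, "nse_slope_std": 0.0}
    yz = (y - y.mean()) / y.std(ddof=1)
    dz = (DIST_ARR - DIST_ARR.mean()) / DIST_ARR.std(ddof=1)
    mz = (DIGIT_ARR - DIGIT_ARR.mean()) / DIGIT_ARR.std(ddof=1)
    coef, _ = _ols(yz, np.column_stack([dz, mz]))
    return {"nde_slope_std": float(coef[1]), "nse_slope_std": float(coef[2])}


def fit_snarc(table: pd.DataFrame) -> float:
    """SNARC slope of one participant from a preprocessed trial table.

    Computes dRT(d) = mean RT(right-hand responses) - mean RT(left-hand
    responses) per digit and returns the OLS slope of dRT on digit
    magnitude.  Both blocks are needed: within a block each digit is
    (correctly) answered with exactly one hand, so the right/left contrast
    for a digit only exists across the two reversed-mapping blocks.
    """
    cell = table.groupby(["number", "response_side"])["rt_ms"].mean().unstack()
    for side in ("left", "right"):
        if side not in cell.columns:
            cell[side] = np.nan
    drt = (cell["right"] - cell["left"]).reindex(list(DIGITS))
    if drt.isna().any():
        missing = drt.index[drt.isna()].tolist()
        raise ValueError(f"digit(s) {missing} lack left- or right-hand trials")
    y = drt.to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0
    coef, _ = _ols(y, DIGIT_ARR[:, None])
    return float(coef[1])


def fit_all_participants(
    table: pd.DataFrame,
    min_cell: int = 5,
    include_snarc: bool = False,
    include_standardized: bool = False,
) -> pd.DataFrame:
    """Slope table: one row per participant with all effect estimates.

    Expects a preprocessed table (retained correct trials only).  Columns:
    participant_id, group, intercept, nde_slope, nse_slope, ratio_slope,
    r_squared, mean_rt, sd_rt (+ snarc_slope / standardized slopes on
    request).
    """
    means = aggregate_digit_means(table, min_cell=min_cell)
    means_wide = means.pivot(index="participant_id", columns="number",
                             values="mean_rt")[list(DIGITS)]
    rows = []
    for pid, sub in table.groupby("participant_id"):
        m8 = means_wide.loc[pid].to_numpy(dtype=float)
        rec = {"participant_id": pid, "group": sub["group"].iloc[0]}
        rec.update(fit_distance_size(m8))
        rec["ratio_slope"] = fit_ratio(m8)
        rts = sub["rt_ms"]
        rec["mean_rt"] = float(rts.mean())
        rec["sd_rt"] = float(rts.std(ddof=1))
        if include_standardized:
            rec.update(standardize_slopes(m8))
        if include_snarc:
            rec["snarc_slope"] = fit_snarc(sub)
        rows.append(rec)
    return pd.DataFrame(rows)
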