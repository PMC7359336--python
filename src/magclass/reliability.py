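"""Split-half reliability of the slope measures and correlation utilities.

Reliability is estimated by randomly splitting each participant's retained
trials into two halves (stratified by digit x block so each half preserves
the design), fitting the effect slope on each half, correlating half-1 with
half-2 slopes across participants, averaging that correlation over many
random splits, and applying the Spearman-Brown correction for double test
length.  Also provides the attenuation ("correction for unreliability") and
partial-correlation formulas used when relating effect measures to each
other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DIGITS, W_DISTANCE, W_MAGNITUDE, ratio, DIGIT_ARR

_RATIO = ratio(DIGIT_ARR)
_RATIO_C = _RATIO - _RATIO.mean()
W_RATIO = _RATIO_C / (_RATIO_C @ _RATIO_C)

_SLOPE_W = {"nde": W_DISTANCE, "nse": W_MAGNITUDE, "ratio": W_RATIO}


@dataclass
class ReliabilityEstimate:
    effect: str
    r_half: float
    r_sb: float
    n_splits: int
    seed: int


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full (double) test length: 2r/(1+r)."""
    if r <= -1.0:
        raise ValueError("Spearman-Brown is undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    table: pd.DataFrame,
    effect: str = "nde",
    n_splits: int = 1000,
    seed: int = 0,
    singleton_policy: str = "random",
) -> ReliabilityEstimate:
    """Split-half reliability of a slope measure, Spearman-Brown corrected.

    `table` is the preprocessed trial table.  Cells (participant x digit x
    block) with a single trial are assigned to a random half
    (``singleton_policy="random"``) or dropped (``"exclude"``).  Correlations
    are averaged across splits on the raw r scale.
    """
    if effect not in _SLOPE_W:
        raise ValueError(f"unknown effect {effect!r}; choose from {sorted(_SLOPE_W)}")
    if singleton_policy not in ("random", "exclude"):
        raise ValueError("singleton_policy must be 'random' or 'exclude'")
    w = _SLOPE_W[effect]
    rng = np.random.default_rng(seed)

    # per participant: list of 8 digit entries, each a list of per-block RT arrays
    digit_pos = {d: i for i, d in enumerate(DIGITS)}
    cohort: dict[str, list[list[np.ndarray]]] = {}
    for (pid, number, _block), sub in table.groupby(
        ["participant_id", "number", "block"]
    ):
        rts = sub["rt_ms"].to_numpy(dtype=float)
        cohort.setdefault(pid, [[] for _ in DIGITS])[digit_pos[number]].append(rts)

    pids = sorted(cohort)
    rs = np.empty(n_splits)
    for s in range(n_splits):
        half1 = np.empty((len(pids), 8))
        half2 = np.empty((len(pids), 8))
        for i, pid in enumerate(pids):
            for j, cells in enumerate(cohort[pid]):
                s1_sum = s1_n = s2_sum = s2_n = 0.0
                for rts in cells:
                    n = rts.size
                    if n == 1:
                        if singleton_policy == "exclude":
                            continue
                        if rng.random() < 0.5:
                            s1_sum += rts[0]; s1_n += 1
                        else:
                            s2_sum += rts[0]; s2_n += 1
                        continue
                    perm = rng.permutation(n)
                    k = n // 2 + (1 if (n % 2 and rng.random() < 0.5) else 0)
                    a, b = rts[perm[:k]], rts[perm[k:]]
                    s1_sum += a.sum(); s1_n += a.size
                    s2_sum += b.sum(); s2_n += b.size
                if s1_n == 0 or s2_n == 0:
                    raise ValueError(
                        f"participant {pid!r}, digit {DIGITS[j]}: a half has "
                        "no trials; need >= 2 trials per digit"
                    )
                half1[i, j] = s1_sum / s1_n
                half2[i, j] = s2_sum / s2_n
        slopes1 = half1 @ w
        slopes2 = half2 @ w
        rs[s] = np.corrcoef(slopes1, slopes2)[0, 1]
    r_half = float(np.mean(rs))
    return ReliabilityEstimate(effect=effect, r_half=r_half,
                               r_sb=spearman_brown(r_half),
                               n_splits=n_splits, seed=seed)


def attenuation_corrected_correlation(r_xy: float, rel_x: float, rel_y: float) -> float:
    """Correlation corrected for measurement unreliability.

    r_true = r_xy / sqrt(rel_x * rel_y), clipped to [-1, 1] (a warning is
    emitted when clipping occurs, which signals reliabilities inconsistent
    with the observed correlation).
    """
    if rel_x <= 0 or rel_y <= 0:
        raise ValueError("reliabilities must be positive")
    if rel_x > 1 or rel_y > 1:
        raise ValueError("reliabilities cannot exceed 1")
    out = r_xy / np.sqrt(rel_x * rel_y)
    if abs(out) > 1.0:
        import warnings

        warnings.warn(
            f"disattenuated correlation {out:.3f} outside [-1, 1]; clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        out = float(np.clip(out, -1.0, 1.0))
    return float(out)


def partial_correlation(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r_xy.z with its t-based p-value.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)); the p-value
    uses t = r sqrt((n-3)/(1-r^2)) on n-3 df (two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for a first-order partial correlation")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"{name} has zero variance")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise ValueError("a control correlation is +/-1; partial correlation undefined")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 3) / (1 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return r, float(p)
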