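"""Individual-level classification of distance/size effects by H0 bootstrap.

The null hypothesis is that a participant's RTs do not depend on the digit
presented.  It is simulated by resampling, with replacement, 8 sets of
`set_size` RTs from the participant's pooled retained correct RTs, labelling
the sets arbitrarily with the 8 digits, and fitting the same distance+size
regression used for the empirical slopes.  Repeating this `n_iter` times
yields a per-participant null slope distribution; an empirical slope lying
outside the mid 90% of that distribution in the typical (resp. opposite)
direction marks a reliable typical (resp. reliable reverse) effect.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import W_DISTANCE, W_MAGNITUDE

#: direction of the typical effect per slope measure
TYPICAL_SIGN = {"nde": -1.0, "nse": +1.0}

LABELS = ("reliable_typical", "reliable_reverse", "not_reliable")


@dataclass
class BootstrapClassification:
    participant_id: str
    effect: str
    empirical_slope: float
    ci90: tuple[float, float]
    label: str
    null_slopes: np.ndarray


def participant_rng(master_seed: int, participant_id: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one participant.

    Derived from (master seed, stable hash of the participant id) so serial
    and parallel runs agree regardless of cohort ordering.
    """
    digest = hashlib.sha256(str(participant_id).encode("utf-8")).digest()
    pid_key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), pid_key]))


def h0_bootstrap(
    rts,
    n_iter: int = 5000,
    set_size: int = 60,
    seed=None,
    min_pool: int = 50,
) -> dict[str, np.ndarray]:
    """Null slope distributions for the distance and size effects.

    `rts` is the participant's pool of retained correct RTs (all digits and
    blocks pooled).  Returns {"nde": array(n_iter), "nse": array(n_iter)}.
    Deterministic given the RNG / seed.
    """
    pool = np.asarray(rts, dtype=float)
    pool = pool[np.isfinite(pool)]
    if pool.size < min_pool:
        raise ValueError(
            f"RT pool has {pool.size} trials; at least {min_pool} required "
            "for a meaningful null distribution"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, pool.size, size=(n_iter, 8, set_size))
    set_means = pool[idx].mean(axis=2)          # (n_iter, 8), ordered as DIGITS
    # centring each iteration's means is a no-op analytically (the contrast
    # weights sum to 0) but makes constant pools give exactly zero slopes
    set_means = set_means - set_means.mean(axis=1, keepdims=True)
    return {
        "nde": set_means @ W_DISTANCE,
        "nse": set_means @ W_MAGNITUDE,
    }


def classify(
    empirical_slope: float,
    null_slopes,
    ci: float = 0.90,
    effect: str = "nde",
) -> tuple[str, tuple[float, float]]:
    """3-way label from the empirical slope and its H0 distribution.

    CI bounds are the (100*(1-ci)/2, 100*(1+ci)/2) percentiles (linear
    interpolation between order statistics).  A slope exactly on a bound
    counts as inside.  Returns (label, (low, high)).
    """
    if not np.isfinite(empirical_slope):
        raise ValueError("empirical slope must be finite")
    if effect not in TYPICAL_SIGN:
        raise ValueError(f"unknown effect {effect!r}")
    null_slopes = np.asarray(null_slopes, dtype=float)
    if null_slopes.size == 0:
        raise ValueError("null slope distribution is empty")
    alpha = (1.0 - ci) / 2.0
    low, high = np.percentile(null_slopes, [100 * alpha, 100 * (1 - alpha)])
    outside = empirical_slope < low or empirical_slope > high
    if not outside:
        return "not_reliable", (float(low), float(high))
    typical = empirical_slope * TYPICAL_SIGN[effect] > 0
    return ("reliable_typical" if typical else "reliable_reverse"), (float(low), float(high))


def classify_cohort(
    table: pd.DataFrame,
    slopes: pd.DataFrame,
    n_iter: int = 5000,
    set_size: int = 60,
    ci: float = 0.90,
    seed: int = 0,
    min_pool: int = 50,
    keep_null: bool = False,
) -> pd.DataFrame:
    """Bootstrap-classify every participant for both effects.

    `table` is the preprocessed trial table (pool source) and `slopes` the
    output of effects.fit_all_participants.  Returns a tidy frame with one
    row per participant x effect.
    """
    rows = []
    pools = table.groupby("participant_id")["rt_ms"]
    slopes = slopes.set_index("participant_id")
    for pid, rts in pools:
        rng = participant_rng(seed, pid)
        null = h0_bootstrap(rts.to_numpy(), n_iter=n_iter, set_size=set_size,
                            seed=rng, min_pool=min_pool)
        for effect, col in (("nde", "nde_slope"), ("nse", "nse_slope")):
            emp = float(slopes.loc[pid, col])
            label, (lo, hi) = classify(emp, null[effect], ci=ci, effect=effect)
            rec = {
                "participant_id": pid,
                "group": slopes.loc[pid, "group"],
                "effect": effect,
                "empirical_slope": emp,
                "ci_low": lo,
                "ci_high": hi,
                "label": label,
            }
            if keep_null:
                rec["null_slopes"] = null[effect]
            rows.append(rec)
    return pd.DataFrame(rows)


def prevalence_table(classifications: pd.DataFrame, effect: str) -> pd.DataFrame:
    """Counts and integer percentages of each label per group and overall."""
    sub = classifications[classifications["effect"] == effect]
    ct = (
        sub.groupby(["group", "label"]).size()
        .unstack(fill_value=0)
        .reindex(columns=list(LABELS), fill_value=0)
    )
    ct.loc["Overall"] = ct.sum(axis=0)
    pct = ct.div(ct.sum(axis=1), axis=0) * 100.0
    out = ct.copy()
    for lab in LABELS:
        out[f"{lab}_pct"] = pct[lab].round(0).astype(int)
    out["n"] = ct.sum(axis=1)
    return out.reset_index()
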