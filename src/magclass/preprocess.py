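"""Trial screening for RT analysis.

Stages, applied per participant in this order:

1. participant exclusion by overall error rate (confused participants);
2. accuracy summaries with the variance-stabilising arcsine transform
   ``2*arcsin(sqrt(p))``;
3. removal of anticipations: correct responses faster than 200 ms;
4. sequential (recursive) +/- k*SD trimming of the remaining correct RTs.

Trials with a missing RT (response deadline reached) count as errors: they
carry no usable response.  The report keeps exact per-participant accounting:
retained + anticipations + trimmed + errors = total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PreprocessReport:
    """Per-participant and global bookkeeping of the screening stages."""

    per_participant: pd.DataFrame = field(repr=False)
    excluded_participant_ids: list[str] = field(default_factory=list)
    proportion_rt_retained: float = float("nan")
    overall_accuracy: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "excluded_participant_ids": list(self.excluded_participant_ids),
            "proportion_rt_retained": self.proportion_rt_retained,
            "overall_accuracy": self.overall_accuracy,
            "per_participant": self.per_participant.to_dict(orient="records"),
        }


def _is_error(df: pd.DataFrame) -> pd.Series:
    return (~df["correct"].astype(bool)) | df["rt_ms"].isna()


def exclude_by_error_rate(table: pd.DataFrame, threshold: float = 0.40):
    """Drop participants whose error rate is >= threshold.

    Returns (filtered table, list of excluded participant ids).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if table.empty:
        raise ValueError("empty trial table")
    err = _is_error(table).groupby(table["participant_id"]).mean()
    excluded = sorted(err.index[err >= threshold].tolist()) if threshold < 1.0 else []
    kept = table[~table["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def arcsine_accuracy(p):
    """Variance-stabilising transform 2*arcsin(sqrt(p)) of proportions."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportion correct must lie in [0, 1]")
    out = 2.0 * np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def filter_anticipations(table: pd.DataFrame, min_rt_ms: float = 200.0):
    """Remove correct trials with RT strictly below min_rt_ms.

    Returns (table, n_removed).  Operates only on correct trials: error
    trials never enter RT analyses in the first place.
    """
    fast = table["correct"].astype(bool) & (table["rt_ms"] < min_rt_ms)
    return table[~fast].reset_index(drop=True), int(fast.sum())


def _trim_once(rts: np.ndarray, k: float) -> np.ndarray:
    m, s = rts.mean(), rts.std(ddof=1)
    return rts[(rts >= m - k * s) & (rts <= m + k * s)]


def trim_sd(table: pd.DataFrame, k: float = 3.0, mode: str = "recursive"):
    """Per-participant +/- k*SD trimming of correct RTs.

    ``recursive`` repeats mean/SD recomputation and removal until no RT lies
    outside the band; ``single_pass`` does one pass.  Participants with fewer
    than 3 correct RTs are left untouched (SD degenerate).

    Returns (trimmed table, Series of n_trimmed per participant).
    """
    if mode not in ("recursive", "single_pass"):
        raise ValueError(f"unknown trimming mode {mode!r}")
    keep_mask = np.ones(len(table), dtype=bool)
    n_trimmed = {}
    correct = table["correct"].astype(bool) & table["rt_ms"].notna()
    for pid, idx in table.index.groupby(table["participant_id"]).items():
        sel = idx[correct.loc[idx]]
        rts = table.loc[sel, "rt_ms"].to_numpy(dtype=float)
        if rts.size < 3:
            n_trimmed[pid] = 0
            continue
        keep = np.ones(rts.size, dtype=bool)
        while True:
            cur = rts[keep]
            if cur.size < 3:
                break
            m, s = cur.mean(), cur.std(ddof=1)
            out = keep & ((rts < m - k * s) | (rts > m + k * s))
            if not out.any():
                break
            keep &= ~out
            if mode == "single_pass":
                break
        n_trimmed[pid] = int((~keep).sum())
        keep_mask[table.index.get_indexer(sel[~keep])] = False
    trimmed = table[keep_mask].reset_index(drop=True)
    return trimmed, pd.Series(n_trimmed, name="n_trimmed")


def preprocess(
    table: pd.DataFrame,
    error_threshold: float = 0.40,
    min_rt_ms: float = 200.0,
    k: float = 3.0,
    trim_mode: str = "recursive",
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full screening pipeline; returns (RT-analysis table, report).

    The returned table contains only the retained correct trials.  The
    retention denominator is every experimental trial of the non-excluded
    participants, so errors, anticipations and trimmed trials all count as
    lost — this is the bridge from overall accuracy to the proportion of RT
    data analysed.
    """
    table, excluded = exclude_by_error_rate(table, error_threshold)
    totals = table.groupby("participant_id").size()

    errors = _is_error(table)
    acc = 1.0 - errors.groupby(table["participant_id"]).mean()
    n_errors = errors.groupby(table["participant_id"]).sum()

    clean = table[~errors]
    clean, _ = filter_anticipations(clean, min_rt_ms)  # counts recomputed below
    n_antic = (
        (table["correct"].astype(bool) & (table["rt_ms"] < min_rt_ms))
        .groupby(table["participant_id"]).sum()
    )
    retained, n_trimmed = trim_sd(clean, k=k, mode=trim_mode)
    n_kept = retained.groupby("participant_id").size()

    per = pd.DataFrame({
        "n_trials_total": totals,
        "n_errors": n_errors.reindex(totals.index, fill_value=0).astype(int),
        "n_anticipations": n_antic.reindex(totals.index, fill_value=0).astype(int),
        "n_trimmed": n_trimmed.reindex(totals.index, fill_value=0).astype(int),
        "n_retained": n_kept.reindex(totals.index, fill_value=0).astype(int),
        "error_rate": 1.0 - acc.reindex(totals.index),
        "accuracy_transformed": arcsine_accuracy(acc.reindex(totals.index).to_numpy()),
    })
    per.index.name = "participant_id"
    report = PreprocessReport(
        per_participant=per.reset_index(),
        excluded_participant_ids=excluded,
        proportion_rt_retained=float(per["n_retained"].sum() / per["n_trials_total"].sum()),
        overall_accuracy=float(1.0 - per["n_errors"].sum() / per["n_trials_total"].sum()),
    )
    return retained, report
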