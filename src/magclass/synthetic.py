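"""Synthetic magnitude-classification experiments with known ground truth.

Emulates the paradigm: two blocks of 240 trials with reversed response-key
assignment, each digit in {1,2,3,4,6,7,8,9} shown 30 times per block in a
randomised order with no digit repeated more than twice in a row, responses
censored at 2 s.  Each simulated participant has their own baseline RT and
distance / size (and optionally SNARC) slopes drawn from configurable
population distributions; trial noise is ex-Gaussian.  The generator returns
both the trial table and the per-participant generative slopes so that
parameter recovery can be tested downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DIGITS, N_BLOCKS, REPS_PER_BLOCK, distance


class ShuffleInfeasibleError(RuntimeError):
    """No ordering satisfying the run-length constraint was found."""


@dataclass
class SimConfig:
    """Full generative specification of one synthetic experiment.

    Defaults are calibrated to the cohort the pipeline is meant to emulate:
    four groups (13/14/15/56 participants), population distance slope
    N(-13, 8) ms per distance unit, size slope N(1.2, 3.2) ms per magnitude
    unit, and ex-Gaussian trial noise with SD ~90 ms (sigma=50, tau=75),
    giving a grand mean RT near 504 ms and overall accuracy near 97%.

    Parameters
    ----------
    n_per_group
        Mapping from group label to number of participants.
    intercept_dist
        (mean, sd) in ms of the per-participant baseline RT.
    b_dist_dist
        (mean, sd) of the distance slope, ms per distance unit
        (negative = typical distance effect).
    b_size_dist
        (mean, sd) of the size slope, ms per magnitude unit
        (positive = typical size effect).
    b_snarc_dist
        (mean, sd) of the SNARC slope, ms per magnitude unit on the
        right-minus-left RT difference; (0, 0) disables SNARC generation.
    noise
        Ex-Gaussian (mu, sigma, tau) trial noise in ms.
    error_base
        Error probability at distance 0 (extrapolated); per-trial error
        probability is ``error_base * exp(-error_distance_decay * distance)``.
    error_distance_decay
        Non-negative decay rate of error probability with distance,
        reproducing the accuracy distance effect.
    anticipation_rate
        Probability that a trial is an anticipation contaminant with RT
        uniform in (80, 200) ms, random response side, correct w.p. 0.5.
    rt_ceiling_ms
        Response deadline; slower trials are recorded as incorrect with
        missing RT.
    seed
        Master RNG seed; every run with the same config is identical.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"M": 13, "E": 14, "S": 15, "R": 56}
    )
    intercept_dist: tuple[float, float] = (455.0, 70.0)
    b_dist_dist: tuple[float, float] = (-13.0, 8.0)
    b_size_dist: tuple[float, float] = (1.2, 3.2)
    b_snarc_dist: tuple[float, float] = (0.0, 0.0)
    noise: tuple[float, float, float] = (0.0, 50.0, 75.0)
    error_base: float = 0.07
    error_distance_decay: float = 0.35
    anticipation_rate: float = 0.0005
    rt_ceiling_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have >= 1 participant")
        for name in ("error_base", "anticipation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        mu, sigma, tau = self.noise
        if sigma < 0 or tau < 0:
            raise ValueError("noise sigma and tau must be >= 0")
        if self.error_distance_decay < 0:
            raise ValueError("error_distance_decay must be >= 0")
        if self.rt_ceiling_ms <= 200:
            raise ValueError("rt_ceiling_ms must exceed 200 ms")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("intercept_dist", "b_dist_dist", "b_size_dist",
                    "b_snarc_dist", "noise"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def constrained_shuffle(items, max_run: int = 2, seed=None, max_retries: int = 1000):
    """Random permutation of `items` with no symbol run longer than `max_run`.

    Builds the sequence incrementally, at each position sampling among the
    symbols that would not extend a run past `max_run`, weighted by their
    remaining counts.  A dead end triggers a restart; after `max_retries`
    failed attempts the multiset is deemed infeasible.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    items = list(items)
    symbols, counts0 = np.unique(np.asarray(items), return_counts=True)
    n = len(items)
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    for _ in range(max_retries):
        counts = counts0.astype(float).copy()
        out = np.empty(n, dtype=symbols.dtype)
        last_idx, run = -1, 0
        ok = True
        for pos in range(n):
            w = counts.copy()
            if run >= max_run and last_idx >= 0:
                w[last_idx] = 0.0
            total = w.sum()
            if total <= 0:
                ok = False
                break
            pick = rng.choice(len(symbols), p=w / total)
            out[pos] = symbols[pick]
            counts[pick] -= 1
            if pick == last_idx:
                run += 1
            else:
                last_idx, run = pick, 1
        if ok:
            return out.tolist()
    raise ShuffleInfeasibleError(
        f"no ordering with runs <= {max_run} found in {max_retries} attempts"
    )


def sample_ex_gaussian(mu: float, sigma: float, tau: float, n: int, seed=None):
    """Draw n values from Normal(mu, sigma) + Exponential(tau).

    The mean is mu + tau and the variance sigma^2 + tau^2; this is the
    standard positively skewed RT noise model.
    """
    if sigma < 0 or tau < 0:
        raise ValueError("sigma and tau must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.normal(mu, sigma, size=n) + rng.exponential(tau, size=n)


def _block_mapping(first_larger_right: bool, block: int) -> str:
    larger_right = first_larger_right if block == 1 else not first_larger_right
    return "larger_right" if larger_right else "larger_left"


def _simulate_participant(pid, group, first_larger_right, params, config, rng):
    intercept, b_dist, b_size, b_snarc = params
    mu, sigma, tau = config.noise
    rows = []
    for block in (1, 2):
        mapping = _block_mapping(first_larger_right, block)
        seq = constrained_shuffle(
            list(DIGITS) * REPS_PER_BLOCK, max_run=2, seed=rng
        )
        numbers = np.asarray(seq, dtype=int)
        n = numbers.size
        dist = distance(numbers)
        larger = numbers > 5
        if mapping == "larger_right":
            correct_side = np.where(larger, "right", "left")
        else:
            correct_side = np.where(larger, "left", "right")

        p_err = np.clip(
            config.error_base * np.exp(-config.error_distance_decay * dist), 0.0, 1.0
        )
        is_error = rng.random(n) < p_err
        is_antic = rng.random(n) < config.anticipation_rate

        side = np.where(is_error, np.where(correct_side == "right", "left", "right"),
                        correct_side)
        side_sign = np.where(side == "right", 0.5, -0.5)
        noise = rng.normal(mu, sigma, size=n) + (
            rng.exponential(tau, size=n) if tau > 0 else 0.0
        )
        rt = (intercept + b_dist * dist + b_size * numbers
              + side_sign * b_snarc * (numbers - 5) + noise)
        rt = np.maximum(rt, 1.0)
        correct = ~is_error

        # anticipation contaminants override the generative RT model; they are
        # removable downstream purely by the < 200 ms filter
        antic_rt = rng.uniform(80.0, 200.0, size=n)
        antic_correct = rng.random(n) < 0.5
        antic_side = np.where(rng.random(n) < 0.5, "left", "right")
        rt = np.where(is_antic, antic_rt, rt)
        correct = np.where(is_antic, antic_correct, correct)
        side = np.where(is_antic, antic_side, side)

        censored = rt >= config.rt_ceiling_ms
        correct = np.where(censored, False, correct)
        rt = np.where(censored, np.nan, rt)

        rows.append(pd.DataFrame({
            "participant_id": pid,
            "group": group,
            "block": block,
            "trial_index": np.arange(1, n + 1),
            "number": numbers,
            "distance": dist,
            "response_side": side,
            "mapping": mapping,
            "correct": correct.astype(bool),
            "rt_ms": rt,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_experiment(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth slopes).

    Deterministic given ``config.seed``: each participant gets an independent
    RNG stream spawned from the master seed.  Block-order counterbalancing
    alternates across consecutive participants.
    """
    ss = np.random.SeedSequence(config.seed)
    n_total = sum(config.n_per_group.values())
    children = ss.spawn(n_total)
    tables, truths = [], []
    idx = 0
    for group, n in config.n_per_group.items():
        for j in range(n):
            rng = np.random.default_rng(children[idx])
            pid = f"{group}{j + 1:03d}"
            params = (
                rng.normal(*config.intercept_dist),
                rng.normal(*config.b_dist_dist),
                rng.normal(*config.b_size_dist),
                rng.normal(*config.b_snarc_dist),
            )
            tables.append(_simulate_participant(
                pid, group, first_larger_right=(idx % 2 == 0),
                params=params, config=config, rng=rng,
            ))
            truths.append({
                "participant_id": pid, "group": group,
                "intercept": params[0], "b_dist": params[1],
                "b_size": params[2], "b_snarc": params[3],
            })
            idx += 1
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truths)
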