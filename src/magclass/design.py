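"""Constants of the symbolic magnitude-classification task design.

Single-digit Arabic numbers are compared against the fixed standard 5.
The stimulus set excludes 5 itself, so distance |digit - 5| takes values
1-4 on each side and is exactly orthogonal to magnitude over the set.
"""

from __future__ import annotations

import numpy as np

#: Stimulus digits (the standard, 5, is never presented).
DIGITS: tuple[int, ...] = (1, 2, 3, 4, 6, 7, 8, 9)

#: Numerical distance from the standard for each digit, same order as DIGITS.
DISTANCES: tuple[int, ...] = tuple(abs(d - 5) for d in DIGITS)

#: Presentations of each digit per block and number of blocks.
REPS_PER_BLOCK: int = 30
N_BLOCKS: int = 2

DIGIT_ARR = np.asarray(DIGITS, dtype=float)
DIST_ARR = np.asarray(DISTANCES, dtype=float)

# Centred predictors and their sums of squares; used for closed-form OLS
# slopes (valid because distance and magnitude are orthogonal over DIGITS).
_D_C = DIST_ARR - DIST_ARR.mean()
_M_C = DIGIT_ARR - DIGIT_ARR.mean()

#: Weights w such that w @ means = OLS slope on distance (resp. magnitude).
W_DISTANCE = _D_C / (_D_C @ _D_C)
W_MAGNITUDE = _M_C / (_M_C @ _M_C)


def distance(digit):
    """Numerical distance |digit - 5| (vectorised)."""
    return np.abs(np.asarray(digit) - 5)


def ratio(digit):
    """Comparison ratio min(digit, 5) / max(digit, 5), in (0, 1]."""
    d = np.asarray(digit, dtype=float)
    return np.minimum(d, 5.0) / np.maximum(d, 5.0)
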