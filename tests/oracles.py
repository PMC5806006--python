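"""Independent oracles used by the test suite.

These deliberately avoid the package's search/scan code paths: the goal
planner is checked against exhaustive sequence enumeration, and the
frequent-user classifier against a brute-force run-length scanner.
"""

from __future__ import annotations

import itertools
import math

from stepadapt.adaptive import BehaviorParams, engagement_prob, predict_expected_steps


def snap7(m: float) -> float:
    return min(max(int(math.floor(m * 7 + 0.5)), 0), 7) / 7.0


def enumerate_best_plan(
    params: BehaviorParams, m0: float, grid: list[int], horizon: int
) -> tuple[tuple[int, ...], float]:
    """Exhaustive search over all goal sequences under the planner's dynamics.

    Momentum follows the certainty-equivalent update snapped to multiples
    of 1/7; sequence value accumulates backward (v = r_t + v) so floating
    association matches a backward-induction computation.  Sequences are
    visited in ascending lexicographic order and improved strictly, so the
    winner is the lexicographically smallest optimum.
    """
    best_val, best_seq = -math.inf, None
    for seq in itertools.product(grid, repeat=horizon):
        m = snap7(m0)
        rewards = []
        for g in seq:
            rewards.append(predict_expected_steps(params, g, m))
            pi = engagement_prob(params, g, m)
            m = snap7((6.0 * m + pi) / 7.0)
        v = 0.0
        for r in reversed(rewards):
            v = r + v
        if v > best_val:
            best_val, best_seq = v, seq
    return best_seq, best_val


def brute_force_max_run(active: list[bool]) -> int:
    """Longest run of consecutive inactive days, by direct scan."""
    best = 0
    for is_off, chunk in itertools.groupby(active, key=lambda a: not a):
        if is_off:
            best = max(best, len(list(chunk)))
    return best
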