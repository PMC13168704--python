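"""Closed-form mathematics of the costly bead-sampling task.

The task: a child may draw up to 20 animals (dogs/cats) from a hidden
island whose predominant animal appears with probability ``q`` per draw
(0.6 in the low-evidence condition, 0.8 in the high-evidence condition),
then judges which of two islands they are on.  A correct judgment earns
100 credits; every draw costs ``c`` credits (0, 1 or 4).  Assuming the
judgment follows the majority of the drawn animals (ties resolved by a
fair coin), the probability of being correct after ``n`` draws, the
expected gain, and the reward-maximizing sample size all have exact
binomial expressions, implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

MAX_SAMPLES = 20
REWARD = 100.0

#: cost level name -> unit cost in credits
COST_LEVELS = {"zero": 0, "low": 1, "high": 4}
#: evidence level name -> predominant-animal proportion
EVIDENCE_LEVELS = {"low": 0.6, "high": 0.8}

_COST_BY_C = {v: k for k, v in COST_LEVELS.items()}
_EVIDENCE_BY_Q = {v: k for k, v in EVIDENCE_LEVELS.items()}


@dataclass(frozen=True)
class Condition:
    """One of the six cost x evidence cells of the experiment."""

    cost_level: str
    evidence_level: str
    max_samples: int = MAX_SAMPLES
    reward: float = REWARD

    def __post_init__(self) -> None:
        if self.cost_level not in COST_LEVELS:
            raise ValueError(f"unknown cost level {self.cost_level!r}")
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence level {self.evidence_level!r}")
        if self.max_samples < 1:
            raise ValueError("max_samples must be >= 1")

    @property
    def c(self) -> float:
        """Unit sampling cost in credits."""
        return COST_LEVELS[self.cost_level]

    @property
    def q(self) -> float:
        """Proportion of the predominant animal on the preselected island."""
        return EVIDENCE_LEVELS[self.evidence_level]

    @classmethod
    def from_values(cls, c: float, q: float) -> "Condition":
        return cls(_COST_BY_C[c], _EVIDENCE_BY_Q[q])

    @property
    def label(self) -> str:
        return f"cost_{self.cost_level}/evid_{self.evidence_level}"


#: the six experimental conditions, cost-major order
ALL_CONDITIONS = tuple(
    Condition(cost, evid) for cost in COST_LEVELS for evid in EVIDENCE_LEVELS
)


def _check_domain(n: int, q: float, max_samples: int = MAX_SAMPLES) -> None:
    if not 0 <= n <= max_samples:
        raise ValueError(f"sample count n={n} outside [0, {max_samples}]")
    if not 0.0 < q < 1.0:
        raise ValueError(f"proportion q={q} outside (0, 1)")


def correct_prob(n: int, q: float) -> float:
    """Probability that a majority judgment after ``n`` draws is correct.

    Equals P(strict majority matches the predominant animal) plus half
    the probability of a tie (fair-coin tie break); ``n = 0`` is a pure
    guess and returns exactly 0.5.
    """
    n = int(n)
    _check_domain(n, q)
    if n == 0:
        return 0.5
    k = np.arange(n + 1)
    pmf = binom.pmf(k, n, q)
    strict = pmf[2 * k > n].sum()
    tie = pmf[n // 2] if n % 2 == 0 else 0.0
    return float(strict + 0.5 * tie)


def expected_gain(n: int, q: float, c: float) -> float:
    """Expected credits from stopping after ``n`` draws: (100 - n*c) * p(n|q)."""
    if c < 0:
        raise ValueError("unit cost must be non-negative")
    return (REWARD - n * c) * correct_prob(n, q)


#: gains closer than this (in credits) are treated as exact ties; the
#: parity identity makes p(2k) = p(2k-1) mathematically equal but float
#: summation can separate them by ~1e-14
_TIE_TOL = 1e-9


def optimal_n(q: float, c: float, max_samples: int = MAX_SAMPLES) -> int:
    """Reward-maximizing sample size; ties broken toward fewer samples."""
    gains = np.array([expected_gain(n, q, c) for n in range(max_samples + 1)])
    return int(np.nonzero(gains >= gains.max() - _TIE_TOL)[0][0])


def max_gain(q: float, c: float) -> float:
    return expected_gain(optimal_n(q, c), q, c)


def efficiency(n_obs: int, q: float, c: float) -> float:
    """Expected gain at the observed sample count relative to the optimum.

    This is the per-trial sampling-efficiency outcome: 1 means the child
    sampled a reward-maximizing number of animals.
    """
    m = max_gain(q, c)
    if m <= 0:
        raise ValueError("degenerate condition: maximum expected gain <= 0")
    return expected_gain(n_obs, q, c) / m


def signed_deviation(n_obs: int, q: float, c: float) -> int:
    """Observed sample count minus the optimal one (negative = undersampling)."""
    _check_domain(int(n_obs), q)
    return int(n_obs) - optimal_n(q, c)


@dataclass(frozen=True)
class GainProfile:
    """Per-condition table of p(correct) and expected gain over n = 0..20."""

    condition: Condition
    p_correct: np.ndarray = field(repr=False)
    expected_gain: np.ndarray = field(repr=False)
    optimal_n: int = 0
    max_gain: float = 0.0


def gain_profile(condition: Condition) -> GainProfile:
    """Full gain landscape for one condition."""
    q, c = condition.q, condition.c
    ns = range(condition.max_samples + 1)
    p = np.array([correct_prob(n, q) for n in ns])
    g = np.array([expected_gain(n, q, c) for n in ns])
    n_star = optimal_n(q, c, condition.max_samples)
    return GainProfile(condition, p, g, n_star, float(g[n_star]))
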