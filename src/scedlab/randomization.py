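"""Per-participant randomization tests and group-level p-value combination.

The primary inference engine for the multiple-baseline design.  For each
participant the observed effect size is a Cohen *d* comparing the baseline
weekly scores (phase A) with the intervention weekly scores (phases B and
B2), signed so that therapeutic change is positive.  A one-sided Monte-Carlo
p-value is obtained by recomputing *d* over resampled datasets:

* ``label_permutation`` (default): every resample randomly reassigns the
  pooled scores to pseudo-phases of the original sizes;
* ``startpoint_shift``: resamples move the intervention start point over
  the admissible weeks (at least two points on each side), preserving the
  temporal order of the series — the scheme consistent with the staggered
  design randomization.

The p-value is the fraction of resampled effect sizes at least as large as
the observed one, floored at ``1/n_resamples`` (a Monte-Carlo p is never 0).

Individual p-values are combined additively (Edgington's method): under the
group null each individual p is Uniform(0,1), so the sum of n of them
follows the Irwin-Hall distribution, whose exact CDF at the observed sum is
the group p-value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Direction",
    "Scheme",
    "CombinationMethod",
    "PhaseComparison",
    "RandomizationResult",
    "GroupCombination",
    "DegenerateVarianceError",
    "cohens_d",
    "randomization_p",
    "irwin_hall_cdf",
    "combine_p",
    "effect_size_label",
]


class Direction(str, enum.Enum):
    DECREASE_IS_EFFECT = "decrease_is_effect"  # e.g. problem-behavior scores
    INCREASE_IS_EFFECT = "increase_is_effect"  # e.g. positive-following counts


class Scheme(str, enum.Enum):
    LABEL_PERMUTATION = "label_permutation"
    STARTPOINT_SHIFT = "startpoint_shift"


class CombinationMethod(str, enum.Enum):
    IRWIN_HALL_EXACT = "irwin_hall_exact"
    NORMAL_APPROX = "normal_approx"
    MONTE_CARLO = "monte_carlo"


class DegenerateVarianceError(ValueError):
    """Pooled standard deviation is zero; the effect size is undefined."""


@dataclass(frozen=True)
class PhaseComparison:
    """Baseline vs intervention values for one participant and measure."""

    baseline_values: tuple[float, ...]
    intervention_values: tuple[float, ...]
    direction: Direction = Direction.DECREASE_IS_EFFECT

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline_values",
                           tuple(float(v) for v in self.baseline_values))
        object.__setattr__(self, "intervention_values",
                           tuple(float(v) for v in self.intervention_values))

    @property
    def meets_inclusion_rule(self) -> bool:
        """At least 2 measurement points in each phase."""
        return len(self.baseline_values) >= 2 and len(self.intervention_values) >= 2


@dataclass(frozen=True)
class RandomizationResult:
    d_obs: float
    p: float
    n_resamples: int
    scheme: Scheme
    rng_seed: int | None = None


@dataclass(frozen=True)
class GroupCombination:
    individual_ps: tuple[float, ...]
    S: float
    group_p: float
    method: CombinationMethod


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    return math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))


def cohens_d(comparison: PhaseComparison) -> float:
    """Standardized mean difference, positive in the therapeutic direction.

    Uses the (n-1)-weighted pooled standard deviation.  For
    ``decrease_is_effect`` the difference is baseline minus intervention, so
    a score drop during intervention gives a positive *d*; the sign flips
    for ``increase_is_effect``.
    """
    a = np.asarray(comparison.baseline_values, dtype=float)
    b = np.asarray(comparison.intervention_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per phase")
    sp = _pooled_sd(a, b)
    if sp == 0.0:
        raise DegenerateVarianceError("pooled SD is zero")
    diff = a.mean() - b.mean()
    if comparison.direction is Direction.INCREASE_IS_EFFECT:
        diff = -diff
    return diff / sp


def _d_from_groups(mean_a, var_a, n_a, mean_b, var_b, n_b, flip: bool):
    """Vectorized signed d; degenerate resamples map to signed infinity."""
    sp = np.sqrt(((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2))
    diff = mean_a - mean_b
    if flip:
        diff = -diff
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / sp
    d = np.where(sp > 0, d, np.where(diff == 0, 0.0, np.copysign(np.inf, diff)))
    return d


def randomization_p(
    comparison: PhaseComparison,
    n_resamples: int = 1000,
    scheme: Scheme | str = Scheme.LABEL_PERMUTATION,
    rng: np.random.Generator | int | None = None,
) -> RandomizationResult:
    """One-sided Monte-Carlo randomization test for one participant.

    Returns the observed Cohen *d* and ``p = #{d* >= d_obs} / n_resamples``,
    floored at ``1/n_resamples``.  Raises
    :class:`DegenerateVarianceError` when the observed series is constant.
    """
    scheme = Scheme(scheme)
    if not comparison.meets_inclusion_rule:
        raise ValueError("inclusion rule: need >= 2 points in each phase")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()
    d_obs = cohens_d(comparison)  # surfaces the degenerate-variance error

    a = np.asarray(comparison.baseline_values)
    b = np.asarray(comparison.intervention_values)
    flip = comparison.direction is Direction.INCREASE_IS_EFFECT
    na = len(a)
    pooled = np.concatenate([a, b])

    if scheme is Scheme.LABEL_PERMUTATION:
        mat = rng.permuted(np.tile(pooled, (n_resamples, 1)), axis=1)
        ga, gb = mat[:, :na], mat[:, na:]
    else:  # startpoint_shift: series in temporal order, split point moves
        n = len(pooled)
        starts = np.arange(2, n - 1)  # >= 2 points on each side
        if len(starts) < 2:
            raise ValueError(
                "startpoint_shift needs at least 2 admissible start points"
            )
        draws = rng.choice(starts, size=n_resamples)
        d_star = np.empty(n_resamples)
        for s in np.unique(draws):
            idx = draws == s
            ga_s, gb_s = pooled[:s], pooled[s:]
            d_star[idx] = _d_from_groups(
                ga_s.mean(), ga_s.var(ddof=1), s,
                gb_s.mean(), gb_s.var(ddof=1), len(gb_s), flip,
            )
        return _finish(d_obs, d_star, n_resamples, scheme, seed)

    d_star = _d_from_groups(
        ga.mean(axis=1), ga.var(axis=1, ddof=1), na,
        gb.mean(axis=1), gb.var(axis=1, ddof=1), len(b), flip,
    )
    return _finish(d_obs, d_star, n_resamples, scheme, seed)


def _finish(d_obs, d_star, n_resamples, scheme, seed) -> RandomizationResult:
    count = int(np.count_nonzero(d_star >= d_obs - 1e-12))
    p = max(count, 1) / n_resamples
    return RandomizationResult(float(d_obs), p, n_resamples, scheme, seed)


def irwin_hall_cdf(x: float, n: int) -> float:
    """Exact CDF of the sum of ``n`` independent Uniform(0,1) variables.

    Evaluates the alternating-sum polynomial

    ``P(S <= x) = (1/n!) * sum_{k=0}^{floor(x)} (-1)^k C(n,k) (x-k)^n``

    in exact rational arithmetic, which keeps the heavily cancelling sum
    stable well beyond n = 50, then clamps to [0, 1].  Arguments outside
    [0, n] return 0 or 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if x <= 0.0:
        return 0.0
    if x >= n:
        return 1.0
    xf = Fraction(x)
    total = Fraction(0)
    for k in range(int(math.floor(x)) + 1):
        term = math.comb(n, k) * (xf - k) ** n
        total += -term if k % 2 else term
    value = float(total / math.factorial(n))
    return min(1.0, max(0.0, value))


def combine_p(
    individual_ps: Sequence[float],
    method: CombinationMethod | str = CombinationMethod.IRWIN_HALL_EXACT,
    rng: np.random.Generator | int | None = None,
    n_draws: int = 100_000,
) -> GroupCombination:
    """Additive combination of individual p-values into a group p-value.

    Under the joint null each individual p is Uniform(0,1); the group p is
    the probability that the sum of n independent uniforms falls at or below
    the observed sum S.  Methods: exact Irwin-Hall CDF, the normal
    approximation ``Phi((S - n/2) / sqrt(n/12))``, or the empirical fraction
    of ``n_draws`` simulated uniform sums at or below S.
    """
    method = CombinationMethod(method)
    ps = tuple(float(p) for p in individual_ps)
    if not ps:
        raise ValueError("need at least one p-value")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    n = len(ps)
    S = float(sum(ps))
    if method is CombinationMethod.IRWIN_HALL_EXACT:
        gp = irwin_hall_cdf(S, n)
    elif method is CombinationMethod.NORMAL_APPROX:
        gp = float(stats.norm.cdf((S - n / 2.0) / math.sqrt(n / 12.0)))
    else:
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(rng)
        sums = rng.random((n_draws, n)).sum(axis=1)
        gp = float(np.count_nonzero(sums <= S) / n_draws)
    return GroupCombination(ps, S, gp, method)


#: Magnitude annotations for |d| (lower bounds), emitted as labels only.
EFFECT_SIZE_BENCHMARKS = (
    (2.00, "huge"),
    (1.20, "very large"),
    (0.80, "large"),
    (0.50, "medium"),
    (0.20, "small"),
    (0.01, "very small"),
)


def effect_size_label(d: float) -> str:
    """Conventional magnitude label for a Cohen *d* (annotation only)."""
    magnitude = abs(d)
    for bound, label in EFFECT_SIZE_BENCHMARKS:
        if magnitude >= bound:
            return label
    return "negligible"
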