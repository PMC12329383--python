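import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scedlab.randomization import (
    CombinationMethod,
    DegenerateVarianceError,
    Direction,
    PhaseComparison,
    Scheme,
    cohens_d,
    combine_p,
    effect_size_label,
    irwin_hall_cdf,
    randomization_p,
)


def comp(a, b, direction=Direction.DECREASE_IS_EFFECT):
    return PhaseComparison(tuple(a), tuple(b), direction)


def exhaustive_label_p(comparison):
    """Oracle: exact one-sided p over all phase-label assignments."""
    pooled = list(comparison.baseline_values) + list(comparison.intervention_values)
    na = len(comparison.baseline_values)
    d_obs = cohens_d(comparison)
    n_ge = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        try:
            d = cohens_d(comp(a, b, comparison.direction))
        except DegenerateVarianceError:
            diff = np.mean(a) - np.mean(b)
            if comparison.direction is Direction.INCREASE_IS_EFFECT:
                diff = -diff
            d = math.copysign(math.inf, diff) if diff else 0.0
        if d >= d_obs - 1e-12:
            n_ge += 1
    return n_ge / total


class TestCohensD:
    def test_identical_means_give_zero(self):
        assert cohens_d(comp([1, 3], [3, 1])) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # means 12 vs 6, both SDs 2 -> pooled SD 2 -> d = 3
        assert cohens_d(comp([10, 12, 14], [4, 6, 8])) == pytest.approx(3.0)

    def test_direction_flip_negates(self):
        c = comp([10, 12, 14], [4, 6, 8], Direction.INCREASE_IS_EFFECT)
        assert cohens_d(c) == pytest.approx(-3.0)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    @settings(deadline=None, max_examples=60)
    def test_swapping_phases_negates(self, a, b):
        try:
            d1 = cohens_d(comp(a, b))
        except DegenerateVarianceError:
            return
        assert cohens_d(comp(b, a)) == pytest.approx(-d1, abs=1e-9)

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateVarianceError):
            cohens_d(comp([5, 5], [5, 5]))


class TestRandomizationP:
    def test_degenerate_variance_surfaces_not_a_p_value(self):
        with pytest.raises(DegenerateVarianceError):
            randomization_p(comp([2, 2], [2, 2]), rng=0)

    def test_inclusion_rule_enforced(self):
        with pytest.raises(ValueError):
            randomization_p(comp([1.0], [2.0, 3.0]), rng=0)

    def test_p_floored_at_one_over_resamples(self):
        r = randomization_p(comp([9, 8], [1, 2]), n_resamples=200, rng=0)
        assert r.p >= 1 / 200

    def test_separated_phases_smallest_attainable_p(self):
        # exhaustive: only the observed assignment reaches d_obs -> p = 1/6
        c = comp([9, 8], [1, 2])
        assert exhaustive_label_p(c) == pytest.approx(1 / 6)
        r = randomization_p(c, n_resamples=30_000, rng=5)
        se = math.sqrt((1 / 6) * (5 / 6) / 30_000)
        assert abs(r.p - 1 / 6) < 3 * se

    def test_same_seed_reproduces(self):
        c = comp([3, 1, 4, 1], [5, 9, 2, 6])
        assert randomization_p(c, rng=11) == randomization_p(c, rng=11)

    def test_startpoint_shift_needs_two_admissible_starts(self):
        with pytest.raises(ValueError, match="admissible"):
            randomization_p(comp([1, 2], [3, 4]),
                            scheme=Scheme.STARTPOINT_SHIFT, rng=0)

    def test_startpoint_shift_on_step_series(self):
        # clear level shift at the true start point: few shifted starts beat it
        c = comp([10, 11, 10, 9], [2, 1, 2, 3])
        r = randomization_p(c, n_resamples=4000,
                            scheme=Scheme.STARTPOINT_SHIFT, rng=1)
        assert r.scheme is Scheme.STARTPOINT_SHIFT
        # 5 admissible starts, exactly one (the true one) attains d_obs
        assert r.p == pytest.approx(1 / 5, abs=3 * math.sqrt(0.2 * 0.8 / 4000))


class TestIrwinHall:
    def test_single_uniform_is_identity(self):
        assert irwin_hall_cdf(0.5, 1) == pytest.approx(0.5)

    def test_triangular_symmetry(self):
        assert irwin_hall_cdf(1.0, 2) == pytest.approx(0.5)

    def test_out_of_range_clamps(self):
        assert irwin_hall_cdf(-0.3, 4) == 0.0
        assert irwin_hall_cdf(4.7, 4) == 1.0

    def test_completer_group_cell(self):
        # sum of the eight completer p-values = 3.091 -> .14 at 2 dp
        assert irwin_hall_cdf(3.091, 8) == pytest.approx(0.1356, abs=5e-4)
        assert round(irwin_hall_cdf(3.091, 8), 2) == 0.14

    @pytest.mark.parametrize("n", [2, 5, 8, 13, 50])
    def test_matches_scipy_reference(self, n):
        xs = np.linspace(0.2, n - 0.2, 9)
        ours = [irwin_hall_cdf(float(x), n) for x in xs]
        ref = stats.irwinhall.cdf(xs, n)
        assert np.allclose(ours, ref, atol=1e-12)

    @given(st.integers(1, 20), st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=60)
    def test_monotone_nondecreasing(self, n, u, v):
        x, y = sorted((u * n, v * n))
        assert irwin_hall_cdf(x, n) <= irwin_hall_cdf(y, n) + 1e-15


class TestCombineP:
    def test_single_p_passes_through(self):
        assert combine_p([0.5]).group_p == pytest.approx(0.5)

    def test_all_ones_give_one(self):
        assert combine_p([1.0] * 6).group_p == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_p([])

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            combine_p([0.0, 0.5])

    def test_methods_agree_on_moderate_sums(self, rng):
        ps = [0.2, 0.68, 0.5, 0.92, 0.24, 0.001, 0.27, 0.28]
        exact = combine_p(ps, CombinationMethod.IRWIN_HALL_EXACT).group_p
        normal = combine_p(ps, CombinationMethod.NORMAL_APPROX).group_p
        mc = combine_p(ps, CombinationMethod.MONTE_CARLO, rng=rng,
                       n_draws=200_000).group_p
        assert round(exact, 2) == 0.14
        assert normal == pytest.approx(exact, abs=0.02)
        se = math.sqrt(exact * (1 - exact) / 200_000)
        assert mc == pytest.approx(exact, abs=3 * se)


def test_effect_size_labels_match_benchmarks():
    assert effect_size_label(2.04) == "huge"
    assert effect_size_label(-1.44) == "very large"
    assert effect_size_label(0.86) == "large"
    assert effect_size_label(0.49) == "small"
    assert effect_size_label(0.002) == "negligible"
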