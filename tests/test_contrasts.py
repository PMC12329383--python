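import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scedlab.core_io import Dropout, Measure, Phase
from scedlab.contrasts import (
    cohens_d_timepoints,
    completer_filter,
    contrast_table,
    timepoint_stats,
    timepoint_values,
    wilcoxon_signed_rank,
)


class TestTimepointStats:
    def test_positive_following_pretreatment_descriptives(self, study_dataset):
        values = timepoint_values(study_dataset, Measure.DPICS_PF, Phase.T0)
        st_ = timepoint_stats(values)
        assert st_.n == 9
        assert round(st_.mean, 2) == 5.11
        assert round(st_.sd, 2) == 5.64
        assert (st_.min, st_.max) == (0.0, 18.0)

    def test_single_value_has_undefined_sd(self):
        st_ = timepoint_stats([7.0])
        assert st_.mean == 7.0 and st_.sd is None

    def test_all_equal_values_have_zero_sd(self):
        assert timepoint_stats([4.0, 4.0, 4.0]).sd == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            timepoint_stats([])

    def test_dropped_intervention_excluded_after_t0(self, study_dataset):
        t0 = timepoint_values(study_dataset, Measure.DPICS_PF, Phase.T0)
        t1 = timepoint_values(study_dataset, Measure.DPICS_PF, Phase.T1)
        assert "12" in t0 and "12" not in t1


def exhaustive_signed_rank_p(diffs):
    """Oracle: enumerate all 2^n sign assignments on the ranked |diffs|."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    lows = highs = 0
    n = len(diffs)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        lows += w <= w_obs + 1e-9
        highs += w >= w_obs - 1e-9
    total = 2**n
    return min(1.0, 2 * min(lows / total, highs / total))


class TestWilcoxon:
    def test_identical_pairs_vacuous(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_three_positive_pairs(self):
        _, p = wilcoxon_signed_rank([5, 6, 7], [1, 2, 3])
        assert p == pytest.approx(0.25)

    @pytest.mark.parametrize("pattern", list(itertools.product([-1, 1], repeat=5)))
    def test_matches_exhaustive_enumeration_n5(self, pattern):
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0]) * pattern
        pre = np.zeros(5)
        _, p = wilcoxon_signed_rank(pre + post, pre)
        assert p == pytest.approx(exhaustive_signed_rank_p(post))

    def test_ties_handled_exactly(self):
        pre = [5.0, 5.0, 2.0, 9.0]
        post = [3.0, 3.0, 4.0, 2.0]  # diffs 2, 2, -2, 7 with midranks
        _, p = wilcoxon_signed_rank(pre, post)
        assert p == pytest.approx(exhaustive_signed_rank_p(np.subtract(pre, post)))

    def test_agrees_with_scipy_exact_when_no_ties(self, rng):
        pre = rng.normal(size=12)
        post = pre + rng.normal(size=12) + 0.4
        _, p = wilcoxon_signed_rank(pre, post)
        ref = stats.wilcoxon(pre - post, method="exact").pvalue
        assert p == pytest.approx(float(ref))

    @given(
        diffs=st.lists(st.integers(-9, 9), min_size=2, max_size=9),
        shift=st.integers(-5, 5),
    )
    @settings(deadline=None, max_examples=40)
    def test_invariant_to_common_shift_of_both_members(self, diffs, shift):
        if all(d == 0 for d in diffs):
            return
        pre = np.arange(len(diffs), dtype=float)
        post = pre - np.asarray(diffs, float)
        _, p1 = wilcoxon_signed_rank(pre, post)
        _, p2 = wilcoxon_signed_rank(pre + shift, post + shift)
        assert p1 == pytest.approx(p2)

    def test_reproduces_reported_pre_post_p_values(self, study_dataset):
        """Complete-case pre/post pairs yield the reported .01 and .05."""
        for measure, expected in ((Measure.DPICS_PF, 0.01),
                                  (Measure.DPICS_NL, 0.05)):
            t0 = timepoint_values(study_dataset, measure, Phase.T0)
            t1 = timepoint_values(study_dataset, measure, Phase.T1)
            shared = sorted(set(t0) & set(t1))
            _, p = wilcoxon_signed_rank([t0[k] for k in shared],
                                        [t1[k] for k in shared])
            assert round(p, 2) == expected


class TestCohensDTimepoints:
    def test_equal_means_zero_under_both_variants(self):
        a = [1.0, 2.0, 3.0]
        b = [3.0, 2.0, 1.0]
        assert cohens_d_timepoints(a, b, "pooled") == pytest.approx(0.0)
        assert cohens_d_timepoints(a, b, "paired") == pytest.approx(0.0)

    def test_pooled_closed_form(self):
        assert cohens_d_timepoints([8, 10, 12], [2, 4, 6], "pooled") \
            == pytest.approx(3.0)

    def test_variants_disagree_in_general(self):
        a = [10.0, 20.0, 30.0]
        b = [9.0, 18.0, 27.0]
        pooled = cohens_d_timepoints(a, b, "pooled")
        paired = cohens_d_timepoints(a, b, "paired")
        assert pooled != pytest.approx(paired)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d_timepoints([1.0, 1.0], [2.0, 2.0], "pooled")


class TestCompleterFilter:
    def test_all_completers_is_identity(self, study_dataset):
        completers_only = completer_filter(study_dataset)
        expected = [p.participant_id for p in study_dataset.participants
                    if p.dropout_status is Dropout.COMPLETER]
        assert completers_only.participant_ids == expected

    def test_include_dropped_intervention_flag(self, study_dataset):
        with_partial = completer_filter(study_dataset,
                                        include_dropped_intervention=True)
        assert "12" in with_partial.participant_ids

    def test_simulated_mixed_set(self, simulated_dataset):
        kept = completer_filter(simulated_dataset)
        n_completers = sum(
            p.dropout_status is Dropout.COMPLETER
            for p in simulated_dataset.participants
        )
        assert len(kept.participants) == n_completers


class TestContrastTable:
    def test_reproduces_reported_descriptive_cells(self, study_dataset):
        pf = contrast_table(study_dataset, Measure.DPICS_PF)
        nl = contrast_table(study_dataset, Measure.DPICS_NL)
        pf_cells = pf.set_index("timepoint")
        nl_cells = nl.set_index("timepoint")
        assert round(pf_cells.loc["T1", "mean"], 2) == 32.10
        assert round(pf_cells.loc["T2", "mean"], 2) == 32.00
        assert round(pf_cells.loc["T2", "sd"], 2) == 13.49
        assert round(nl_cells.loc["T1", "mean"], 2) == 14.40
        assert round(nl_cells.loc["T2", "mean"], 2) == 6.43
        contrasts = pf.attrs["contrasts"].set_index("contrast")
        assert round(contrasts.loc["T0-T1", "p_wilcoxon"], 2) == 0.01
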