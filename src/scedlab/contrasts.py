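"""Pre/post/follow-up group descriptives and paired nonparametric contrasts.

Produces the group-outcome table for assessment timepoints T0/T1/T2: sample
size, mean, sample SD and range per timepoint, exact Wilcoxon signed-rank
p-values for the pairwise timepoint contrasts, and Cohen *d* effect sizes
(both a pooled-SD and a paired-difference variant, which disagree in
general and are therefore both reported).

The Wilcoxon test uses the exact permutation null for up to 25 pairs, with
zero differences dropped and tied absolute differences midranked; the exact
distribution with midranks is computed by dynamic programming (tied ranks
are outside the reach of the classic exact tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ASSESSMENT_PHASES,
    Dropout,
    Measure,
    Phase,
    StudyDataset,
)

__all__ = [
    "TimepointStats",
    "timepoint_values",
    "timepoint_stats",
    "wilcoxon_signed_rank",
    "cohens_d_timepoints",
    "completer_filter",
    "contrast_table",
]


@dataclass(frozen=True)
class TimepointStats:
    n: int
    mean: float
    sd: float | None  # undefined (None) for n < 2
    min: float
    max: float


def timepoint_values(
    dataset: StudyDataset,
    measure: Measure,
    timepoint: Phase,
    exclude_dropped_intervention_after_t0: bool = True,
) -> dict[str, float]:
    """Assessment values per participant at one timepoint.

    Participants who dropped out of the intervention but stayed in the study
    are excluded from T1/T2 aggregates (they did not complete treatment, so
    their post scores do not describe the treated group) while their T0
    values are retained.
    """
    if timepoint not in ASSESSMENT_PHASES:
        raise ValueError(f"{timepoint} is not an assessment timepoint")
    values: dict[str, float] = {}
    for series in dataset.participants:
        if (
            exclude_dropped_intervention_after_t0
            and timepoint is not Phase.T0
            and series.dropout_status is Dropout.DROPPED_INTERVENTION
        ):
            continue
        v = series.assessment(measure, timepoint)
        if v is not None:
            values[series.participant_id] = v
    return values


def timepoint_stats(values: Mapping[str, float] | Sequence[float]) -> TimepointStats:
    """Mean, (n-1) SD and range of the non-missing values at one timepoint."""
    arr = np.asarray(
        list(values.values()) if isinstance(values, Mapping) else values,
        dtype=float,
    )
    if arr.size == 0:
        raise ValueError("no values at this timepoint")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return TimepointStats(int(arr.size), float(arr.mean()), sd,
                          float(arr.min()), float(arr.max()))


def _exact_signed_rank_cdf(ranks2: np.ndarray) -> np.ndarray:
    """PMF of W+ over all sign assignments, on the doubled-rank lattice.

    ``ranks2`` holds midranks multiplied by two, which makes them integers;
    the returned array ``pmf[w]`` is P(2*W+ = w).
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Returns ``(W, p)`` where W is the positive-rank sum of ``pre - post``
    differences.  Zero differences are dropped; ties are midranked.  The
    null distribution is exact for up to ``exact_max_n`` nonzero pairs and
    a normal approximation with tie correction beyond that.  If every
    difference is zero the test is vacuous and p = 1 with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must pair up")
    diffs = pre - post
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(diffs))
    w_pos = float(ranks[diffs > 0].sum())
    n = diffs.size
    if n <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        pmf = _exact_signed_rank_cdf(ranks2)
        w2 = int(round(2.0 * w_pos))
        lower = float(pmf[: w2 + 1].sum())
        upper = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        _, p = stats.wilcoxon(diffs, correction=False, method="approx")
        p = float(p)
    return w_pos, p


def cohens_d_timepoints(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: str = "pooled",
) -> float:
    """Effect size between two timepoint samples.

    ``pooled``: difference of means over the (n-1)-weighted pooled SD of the
    two samples (samples need not pair up).  ``paired``: mean paired
    difference standardized by the SD of the differences (samples must pair
    up).  Positive values mean sample_a exceeds sample_b.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if variant == "pooled":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("pooled variant needs >= 2 values per sample")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sp = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                     / (len(a) + len(b) - 2))
        if sp == 0:
            raise ZeroDivisionError("pooled SD is zero")
        return float((a.mean() - b.mean()) / sp)
    if variant == "paired":
        if a.shape != b.shape:
            raise ValueError("paired variant needs paired samples")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            raise ZeroDivisionError("difference SD is zero")
        return float(d.mean() / sd)
    raise ValueError(f"unknown variant {variant!r}")


def completer_filter(
    dataset: StudyDataset,
    include_dropped_intervention: bool = False,
) -> StudyDataset:
    """Restrict a dataset to treatment completers.

    With ``include_dropped_intervention`` participants who left the
    intervention but stayed in the study are retained as well; fully
    dropped-out participants are always removed.
    """
    keep = {Dropout.COMPLETER}
    if include_dropped_intervention:
        keep.add(Dropout.DROPPED_INTERVENTION)
    kept = [p for p in dataset.participants if p.dropout_status in keep]
    ids = {p.participant_id for p in kept}
    return StudyDataset(
        participants=kept,
        session_records={k: v for k, v in dataset.session_records.items() if k in ids},
        design={k: v for k, v in dataset.design.items() if k in ids},
    )


_CONTRAST_PAIRS = (
    (Phase.T0, Phase.T1),
    (Phase.T0, Phase.T2),
    (Phase.T1, Phase.T2),
)


def contrast_table(dataset: StudyDataset, measure: Measure) -> pd.DataFrame:
    """Group-outcome table analogue for one measure.

    One row per timepoint with descriptives, plus the pairwise contrasts:
    exact two-sided Wilcoxon p on the complete-case pairs and both Cohen *d*
    variants (paired d on the complete-case pairs, pooled d on the full
    timepoint samples).
    """
    per_tp = {
        tp: timepoint_values(dataset, measure, tp)
        for tp in (Phase.T0, Phase.T1, Phase.T2)
    }
    rows = []
    for tp, values in per_tp.items():
        if not values:
            continue
        st = timepoint_stats(values)
        rows.append(
            {
                "timepoint": tp.value,
                "n": st.n,
                "mean": st.mean,
                "sd": st.sd,
                "min": st.min,
                "max": st.max,
            }
        )
    contrasts = []
    for pa, pb in _CONTRAST_PAIRS:
        shared = sorted(set(per_tp[pa]) & set(per_tp[pb]))
        if len(shared) < 1:
            continue
        pre = [per_tp[pa][pid] for pid in shared]
        post = [per_tp[pb][pid] for pid in shared]
        _, p = wilcoxon_signed_rank(pre, post)
        entry = {
            "contrast": f"{pa.value}-{pb.value}",
            "n_pairs": len(shared),
            "p_wilcoxon": p,
        }
        try:
            entry["d_paired"] = cohens_d_timepoints(post, pre, "paired")
        except (ValueError, ZeroDivisionError):
            entry["d_paired"] = np.nan
        try:
            entry["d_pooled"] = cohens_d_timepoints(
                list(per_tp[pb].values()), list(per_tp[pa].values()), "pooled"
            )
        except (ValueError, ZeroDivisionError):
            entry["d_pooled"] = np.nan
        contrasts.append(entry)
    table = pd.DataFrame(rows)
    table.attrs["contrasts"] = pd.DataFrame(contrasts)
    return table
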