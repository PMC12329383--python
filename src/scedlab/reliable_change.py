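"""Reliable-change indices and clinical-range classification.

A reliable change index (RCI) standardizes a pre/post difference by the
standard deviation of the difference score under measurement error alone
(the Jacobson-Truax construction):

    RCI = (pre - post) / s_diff,   s_diff = SD_norm * sqrt(2 * (1 - r))

signed so that symptom *decrease* is positive.  |RCI| at or beyond the
instrument threshold indicates change exceeding what measurement error
alone would produce.

Instrument defaults: the ECBI scales use threshold 1.96 with difference-SDs
calibrated from the study's published (raw score, RCI) pairs — Intensity
s_diff = 21.8, Problem s_diff = 4.69.  The OBVL uses threshold 1.645 but
ships without a default s_diff because no single value reproduces the
published OBVL indices; supply one via :class:`ReliabilityParams` to enable
OBVL RCIs.  Clinical cutoffs: ECBI Intensity raw >= 131, ECBI Problem raw
>= 13, OBVL total T >= 60 (higher is clinical).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .core_io import (
    ASSESSMENT_PHASES,
    Measure,
    ParticipantSeries,
    Phase,
    StudyDataset,
)

__all__ = [
    "ReliabilityParams",
    "RCIResult",
    "Classification",
    "ClinicalStatus",
    "Interval",
    "DEFAULT_PARAMS",
    "s_diff_from_norms",
    "rci",
    "classify",
    "clinical_status",
    "rci_table",
    "rci_summary",
]


class Classification(str, enum.Enum):
    IMPROVED = "improved"
    DETERIORATED = "deteriorated"
    NO_RELIABLE_CHANGE = "no_reliable_change"
    NOT_COMPUTABLE = "not_computable"


class ClinicalStatus(str, enum.Enum):
    CLINICAL = "clinical"
    BELOW_CLINICAL = "below_clinical"


class Interval(str, enum.Enum):
    T0T1 = "T0T1"
    T0T2 = "T0T2"
    T1T2 = "T1T2"


_INTERVAL_PHASES: dict[Interval, tuple[Phase, Phase]] = {
    Interval.T0T1: (Phase.T0, Phase.T1),
    Interval.T0T2: (Phase.T0, Phase.T2),
    Interval.T1T2: (Phase.T1, Phase.T2),
}


def s_diff_from_norms(sd_norm: float, reliability_r: float) -> float:
    """Difference-score SD from a normative SD and a test-retest reliability."""
    if not 0.0 <= reliability_r <= 1.0:
        raise ValueError("reliability_r must be in [0, 1]")
    if sd_norm <= 0.0:
        raise ValueError("sd_norm must be positive")
    return sd_norm * math.sqrt(2.0 * (1.0 - reliability_r))


@dataclass(frozen=True)
class ReliabilityParams:
    measure: Measure
    rci_threshold: float
    sd_norm: float | None = None
    reliability_r: float | None = None
    s_diff: float | None = None          # given directly, or derived from norms
    clinical_cutoff: float | None = None
    # Only high_is_clinical instruments occur here; kept explicit for clarity.
    clinical_direction: str = "high_is_clinical"

    def resolved_s_diff(self) -> float | None:
        if self.s_diff is not None:
            if self.s_diff <= 0:
                raise ValueError("s_diff must be positive")
            return self.s_diff
        if self.sd_norm is not None and self.reliability_r is not None:
            return s_diff_from_norms(self.sd_norm, self.reliability_r)
        return None


DEFAULT_PARAMS: dict[Measure, ReliabilityParams] = {
    Measure.ECBI_INTENSITY: ReliabilityParams(
        Measure.ECBI_INTENSITY, rci_threshold=1.96, s_diff=21.8,
        clinical_cutoff=131.0,
    ),
    Measure.ECBI_PROBLEM: ReliabilityParams(
        Measure.ECBI_PROBLEM, rci_threshold=1.96, s_diff=4.69,
        clinical_cutoff=13.0,
    ),
    Measure.OBVL_K: ReliabilityParams(
        Measure.OBVL_K, rci_threshold=1.645, s_diff=None,
        clinical_cutoff=60.0,
    ),
}


@dataclass(frozen=True)
class RCIResult:
    participant_id: str
    measure: Measure
    interval: Interval
    rci_value: float | None
    classification: Classification


def classify(rci_value: float | None, threshold: float) -> Classification:
    """Closed-boundary classification: |RCI| at the threshold counts."""
    if rci_value is None:
        return Classification.NOT_COMPUTABLE
    if rci_value >= threshold:
        return Classification.IMPROVED
    if rci_value <= -threshold:
        return Classification.DETERIORATED
    return Classification.NO_RELIABLE_CHANGE


def rci(
    pre: float | None,
    post: float | None,
    params: ReliabilityParams,
    participant_id: str = "",
    interval: Interval = Interval.T0T1,
) -> RCIResult:
    """RCI for one pre/post pair; missing inputs yield a not-computable marker."""
    s_diff = params.resolved_s_diff()
    if pre is None or post is None or s_diff is None:
        return RCIResult(participant_id, params.measure, interval, None,
                         Classification.NOT_COMPUTABLE)
    value = (pre - post) / s_diff
    return RCIResult(participant_id, params.measure, interval, value,
                     classify(value, params.rci_threshold))


def clinical_status(value: float, params: ReliabilityParams) -> ClinicalStatus:
    """Below-clinical iff the score falls strictly under the cutoff."""
    if params.clinical_cutoff is None:
        raise ValueError(f"no clinical cutoff configured for {params.measure}")
    if value < params.clinical_cutoff:
        return ClinicalStatus.BELOW_CLINICAL
    return ClinicalStatus.CLINICAL


def rci_table(
    dataset: StudyDataset,
    params_by_measure: Mapping[Measure, ReliabilityParams] | None = None,
    intervals: Sequence[Interval] = tuple(Interval),
) -> list[RCIResult]:
    """One RCI per participant x measure x interval, from assessment triplets.

    Cells whose pre or post value is missing, or whose instrument has no
    difference-SD configured, are emitted with a not-computable marker so
    the table shape stays predictable.
    """
    params_by_measure = DEFAULT_PARAMS if params_by_measure is None else params_by_measure
    results: list[RCIResult] = []
    for series in dataset.participants:
        for measure, params in params_by_measure.items():
            if not _has_any_assessment(series, measure):
                continue
            for interval in intervals:
                pre_phase, post_phase = _INTERVAL_PHASES[interval]
                results.append(
                    rci(
                        series.assessment(measure, pre_phase),
                        series.assessment(measure, post_phase),
                        params,
                        participant_id=series.participant_id,
                        interval=interval,
                    )
                )
    return results


def _has_any_assessment(series: ParticipantSeries, measure: Measure) -> bool:
    return any(
        obs.measure is measure and obs.phase in ASSESSMENT_PHASES
        and obs.value is not None
        for obs in series.observations
    )


def rci_summary(results: Sequence[RCIResult]) -> pd.DataFrame:
    """Counts of reliable improvements/deteriorations per measure x interval."""
    rows = []
    keys = sorted({(r.measure, r.interval) for r in results},
                  key=lambda k: (k[0].value, k[1].value))
    for measure, interval in keys:
        cell = [r for r in results if r.measure is measure and r.interval is interval]
        rows.append(
            {
                "measure": measure.value,
                "interval": interval.value,
                "n_computable": sum(
                    r.classification is not Classification.NOT_COMPUTABLE
                    for r in cell
                ),
                "improved": sum(
                    r.classification is Classification.IMPROVED for r in cell
                ),
                "deteriorated": sum(
                    r.classification is Classification.DETERIORATED for r in cell
                ),
            }
        )
    return pd.DataFrame(rows)


def results_frame(results: Sequence[RCIResult]) -> pd.DataFrame:
    """Flat table of RCI results (analysis-report export)."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "measure": r.measure.value,
                "interval": r.interval.value,
                "rci": r.rci_value,
                "classification": r.classification.value,
            }
            for r in results
        ]
    )
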