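"""Reference data from the PCIT-VR multiple-baseline study.

The study enrolled 18 parents of 11 children in a community-based clinical
sample; eleven parents contributed pre/post/follow-up assessments.  This
module ships the small published summary tables — per-parent assessment raw
scores with VR practice totals, the reported reliable-change indices, and
the per-parent randomization-test results — so that the analysis engines
can be exercised and cross-validated without any download.

Participant labels are the study's two-digit codes.  A dash in the source
tables (value not collected) is represented as ``None``/``NaN``.  The
reported RCI table is kept verbatim, including two cells that are not
internally consistent with the raw scores (participant 15's Intensity
pre-to-follow-up index and participant 16's Problem column); consistency
checks treat those as print anomalies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import (
    Dropout,
    Measure,
    MeasureObservation,
    ParticipantSeries,
    Phase,
    StudyDataset,
)

__all__ = [
    "assessment_scores",
    "assessment_dataset",
    "vr_totals",
    "reported_rci",
    "reported_randomization",
    "completer_ecbi_pvalues",
]

# Per-parent assessment raw scores and VR practice totals.
# Columns: vr_total, (PF, NL, ECBI-Intensity, ECBI-Problem, OBVL) x (T0, T1, T2).
_ASSESSMENTS: dict[str, dict] = {
    "03": dict(group="A", vr_total=4, pf=(3, 89, None), nl=(14, 0, None),
               intensity=(140, 143, 132), problem=(17, 20, 21), obvl=(72, 68, 66)),
    "05": dict(group="A", vr_total=3, pf=(10, 23, None), nl=(41, 57, None),
               intensity=(159, 161, 131), problem=(18, 22, 5), obvl=(79, 79, 75)),
    "06": dict(group="A", vr_total=3, pf=(6, 28, None), nl=(36, 19, None),
               intensity=(155, 109, 150), problem=(16, 1, 14), obvl=(75, 55, 66)),
    "15": dict(group="A", vr_total=4, pf=(0, 11, 36), nl=(32, 12, 8),
               intensity=(165, 115, 129), problem=(20, 0, 0), obvl=(63, 53, 48)),
    "16": dict(group="A", vr_total=5, pf=(18, 51, 37), nl=(56, 10, 1),
               intensity=(137, 124, 135), problem=(15, 1, 20), obvl=(77, 76, 72)),
    "02": dict(group="B", vr_total=7, pf=(2, 24, 51), nl=(5, 3, 3),
               intensity=(117, 63, 62), problem=(29, 20, 0), obvl=(56, 54, 48)),
    "04": dict(group="B", vr_total=24, pf=(2, 17, 24), nl=(30, 8, 10),
               intensity=(123, 119, 131), problem=(13, 17, 18), obvl=(72, 72, 76)),
    "09": dict(group="B", vr_total=14, pf=(2, 35, 43), nl=(37, 22, 15),
               intensity=(145, 128, 128), problem=(21, 7, 2), obvl=(70, 68, 66)),
    "12": dict(group="B", vr_total=7, pf=(3, 3, 1), nl=(51, 18, 18),
               intensity=(164, 88, 87), problem=(19, 6, 7), obvl=(72, 53, 51)),
    "17": dict(group="B", vr_total=24, pf=(None, 26, 13), nl=(None, 6, 4),
               intensity=(None, 52, 51), problem=(None, 0, 0), obvl=(None, 58, 50)),
    "18": dict(group="B", vr_total=8, pf=(None, 17, 20), nl=(None, 7, 4),
               intensity=(None, 78, 101), problem=(None, 0, 2), obvl=(None, 49, 59)),
}

# Participant 12 left the intervention early but completed study assessments.
_DROPPED_INTERVENTION = {"12"}

_MEASURE_KEYS = {
    "pf": Measure.DPICS_PF,
    "nl": Measure.DPICS_NL,
    "intensity": Measure.ECBI_INTENSITY,
    "problem": Measure.ECBI_PROBLEM,
    "obvl": Measure.OBVL_K,
}

_TIMEPOINTS = (Phase.T0, Phase.T1, Phase.T2)


def assessment_scores() -> pd.DataFrame:
    """Wide per-parent table of assessment raw scores and VR totals."""
    rows = []
    for pid, rec in _ASSESSMENTS.items():
        row = {"participant_id": pid, "group": rec["group"],
               "vr_total": rec["vr_total"]}
        for key in _MEASURE_KEYS:
            for tp, value in zip(("t0", "t1", "t2"), rec[key]):
                row[f"{key}_{tp}"] = np.nan if value is None else float(value)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def assessment_dataset() -> StudyDataset:
    """The assessment scores as a :class:`StudyDataset` (T0/T1/T2 phases)."""
    participants = []
    for pid, rec in _ASSESSMENTS.items():
        status = (Dropout.DROPPED_INTERVENTION if pid in _DROPPED_INTERVENTION
                  else Dropout.COMPLETER)
        obs = []
        for key, measure in _MEASURE_KEYS.items():
            for tp, value in zip(_TIMEPOINTS, rec[key]):
                if value is not None:
                    obs.append(MeasureObservation(pid, measure, 0, tp, float(value)))
        participants.append(ParticipantSeries(pid, status, obs))
    return StudyDataset(participants=participants)


def vr_totals() -> dict[str, int]:
    """Total number of VR practices per parent over the whole treatment."""
    return {pid: rec["vr_total"] for pid, rec in _ASSESSMENTS.items()}


# Reported reliable-change indices, verbatim:
# (intensity, problem, obvl) x (T0->T1, T0->T2, T1->T2).
_REPORTED_RCI: dict[str, dict] = {
    "03": dict(intensity=(-0.14, 0.37, 0.50), problem=(-0.64, -0.85, -0.21),
               obvl=(2.44, 3.66, 1.22)),
    "05": dict(intensity=(-0.09, 1.29, 1.38), problem=(-0.85, 2.77, 3.62),
               obvl=(0.00, 2.38, 2.38)),
    "06": dict(intensity=(2.11, 0.23, -1.88), problem=(3.20, 0.43, -2.77),
               obvl=(11.90, 5.36, -6.55)),
    "15": dict(intensity=(2.29, 7.57, 5.28), problem=(4.26, 4.26, 0.00),
               obvl=(5.95, 8.93, 2.98)),
    "16": dict(intensity=(0.60, 0.09, -0.50), problem=(-0.43, -25.57, -25.14),
               obvl=(0.60, 2.98, 2.38)),
    "02": dict(intensity=(2.48, 2.52, 0.05), problem=(1.92, 6.18, 4.26),
               obvl=(1.22, 4.88, 3.66)),
    "04": dict(intensity=(0.18, -0.37, -0.55), problem=(-0.85, -1.07, -0.21),
               obvl=(0.00, -2.44, -2.44)),
    "09": dict(intensity=(0.78, 0.78, 0.00), problem=(2.98, 4.05, 1.07),
               obvl=(1.22, 2.44, 1.22)),
    "12": dict(intensity=(3.49, 3.53, 0.05), problem=(2.77, 2.56, -0.21),
               obvl=(11.59, 12.80, 1.22)),
    "17": dict(intensity=(None, None, 0.05), problem=(None, None, 0.00),
               obvl=(None, None, 4.88)),
    "18": dict(intensity=(None, None, -1.06), problem=(None, None, 0.43),
               obvl=(None, None, -6.10)),
}

#: Reported RCI cells that do not reproduce from the raw scores (kept
#: verbatim above, excluded from calibration cross-checks).
RCI_PRINT_ANOMALIES = {
    ("15", "intensity", "T0T2"),
    ("15", "intensity", "T1T2"),
    ("16", "problem", "T0T1"),
    ("16", "problem", "T0T2"),
    ("16", "problem", "T1T2"),
    # prints +0.43 for a raw-score increase 0 -> 2; the table's own sign
    # convention (improvement positive) implies -0.43
    ("18", "problem", "T1T2"),
}


def reported_rci() -> pd.DataFrame:
    """Long table of the reported RCIs: participant, scale, interval, rci."""
    rows = []
    for pid, rec in _REPORTED_RCI.items():
        for scale in ("intensity", "problem", "obvl"):
            for interval, value in zip(("T0T1", "T0T2", "T1T2"), rec[scale]):
                rows.append(
                    {
                        "participant_id": pid,
                        "scale": scale,
                        "interval": interval,
                        "rci": np.nan if value is None else value,
                    }
                )
    return pd.DataFrame(rows)


# Per-parent randomization-test results: Cohen d and one-sided p for the
# weekly ECBI Intensity and OBVL-K series (A vs B/B2 phases).
_REPORTED_RANDOMIZATION: dict[str, dict] = {
    "01": dict(ecbi_d=3.59, ecbi_p=0.84, obvl_d=3.59, obvl_p=0.82,
               status=Dropout.DROPPED_FULLY),
    "02": dict(ecbi_d=0.80, ecbi_p=0.20, obvl_d=0.69, obvl_p=0.15,
               status=Dropout.COMPLETER),
    "03": dict(ecbi_d=0.394, ecbi_p=0.68, obvl_d=0.48, obvl_p=0.49,
               status=Dropout.COMPLETER),
    "04": dict(ecbi_d=0.002, ecbi_p=0.50, obvl_d=0.06, obvl_p=0.46,
               status=Dropout.COMPLETER),
    "05": dict(ecbi_d=-0.925, ecbi_p=0.92, obvl_d=-0.47, obvl_p=0.81,
               status=Dropout.COMPLETER),
    "06": dict(ecbi_d=1.44, ecbi_p=0.24, obvl_d=1.60, obvl_p=0.14,
               status=Dropout.COMPLETER),
    "09": dict(ecbi_d=1.36, ecbi_p=0.001, obvl_d=1.39, obvl_p=0.001,
               status=Dropout.COMPLETER),
    "10": dict(ecbi_d=-2.17, ecbi_p=0.10, obvl_d=-1.77, obvl_p=0.10,
               status=Dropout.DROPPED_FULLY),
    "11": dict(ecbi_d=1.74, ecbi_p=0.18, obvl_d=1.76, obvl_p=0.07,
               status=Dropout.DROPPED_FULLY),
    "12": dict(ecbi_d=0.86, ecbi_p=0.25, obvl_d=0.88, obvl_p=0.13,
               status=Dropout.DROPPED_INTERVENTION),
    "13": dict(ecbi_d=0.20, ecbi_p=0.48, obvl_d=0.217, obvl_p=0.43,
               status=Dropout.DROPPED_FULLY),
    "15": dict(ecbi_d=2.04, ecbi_p=0.27, obvl_d=2.04, obvl_p=0.20,
               status=Dropout.COMPLETER),
    "16": dict(ecbi_d=0.49, ecbi_p=0.28, obvl_d=0.32, obvl_p=0.32,
               status=Dropout.COMPLETER),
}


def reported_randomization() -> pd.DataFrame:
    """Per-parent reported randomization-test effect sizes and p-values."""
    return pd.DataFrame(
        [
            {
                "participant_id": pid,
                "ecbi_d": rec["ecbi_d"],
                "ecbi_p": rec["ecbi_p"],
                "obvl_d": rec["obvl_d"],
                "obvl_p": rec["obvl_p"],
                "dropout_status": rec["status"].value,
            }
            for pid, rec in _REPORTED_RANDOMIZATION.items()
        ]
    )


def completer_ecbi_pvalues() -> list[float]:
    """Individual ECBI Intensity p-values of the eight treatment completers."""
    return [
        rec["ecbi_p"]
        for rec in _REPORTED_RANDOMIZATION.values()
        if rec["status"] is Dropout.COMPLETER
    ]
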