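"""Data model and long-format text I/O for multiple-baseline SCED studies.

A study is a collection of participants, each carrying an ordered list of
:class:`MeasureObservation` — one weekly questionnaire/observation score or
one pre/post/follow-up assessment value.  Weekly rows live in the design
phases A (baseline), B (intervention), B2 (intervention with the VR add-on)
and C (follow-up); assessment rows carry the pseudo-phases T0/T1/T2.

The interchange format is a comma-delimited long table with header
``participant_id,measure,week_index,phase,value`` (optionally
``dropout_status``); a JSON export covers the full dataset including session
records and design assignments.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence


class Measure(str, enum.Enum):
    """Instruments measured in the study."""

    ECBI_INTENSITY = "ECBI_INTENSITY"  # disruptive-behavior frequency, raw 36-252
    ECBI_PROBLEM = "ECBI_PROBLEM"      # problem count, raw 0-36
    OBVL_K = "OBVL_K"                  # parenting-stress T-score
    DPICS_PF = "DPICS_PF"              # positive-following composite
    DPICS_NL = "DPICS_NL"              # negative-leading composite
    VR_COUNT = "VR_COUNT"              # VR practice count in a week


class Phase(str, enum.Enum):
    A = "A"    # baseline
    B = "B"    # intervention, before the add-on
    B2 = "B2"  # intervention with the VR add-on (B-prime)
    C = "C"    # follow-up weekly phase
    T0 = "T0"  # pretreatment assessment
    T1 = "T1"  # posttreatment assessment
    T2 = "T2"  # follow-up assessment


WEEKLY_PHASES = frozenset({Phase.A, Phase.B, Phase.B2, Phase.C})
ASSESSMENT_PHASES = frozenset({Phase.T0, Phase.T1, Phase.T2})

_PHASE_ORDER = {p: i for i, p in enumerate(Phase)}


class Dropout(str, enum.Enum):
    COMPLETER = "completer"
    DROPPED_INTERVENTION = "dropped_intervention"  # left treatment, stayed in study
    DROPPED_FULLY = "dropped_fully"


#: Permitted closed value ranges per instrument (None = unbounded side).
#: Config-overridable: pass ``ranges=`` to the validators below.
DEFAULT_VALUE_RANGES: dict[Measure, tuple[float | None, float | None]] = {
    Measure.ECBI_INTENSITY: (36.0, 252.0),
    Measure.ECBI_PROBLEM: (0.0, 36.0),
    Measure.OBVL_K: (None, None),
    Measure.DPICS_PF: (0.0, None),
    Measure.DPICS_NL: (0.0, None),
    Measure.VR_COUNT: (0.0, None),
}

_INTEGER_MEASURES = frozenset({Measure.VR_COUNT})


class ValidationError(ValueError):
    """A dataset violates a structural or range invariant."""


class ParseError(ValueError):
    """A text file could not be interpreted; the message names the row."""


@dataclass(frozen=True)
class MeasureObservation:
    """One value for one participant, measure, week and phase.

    ``value`` is ``None`` for a missing (administered but unanswered)
    measurement; downstream statistics use complete-case handling.
    """

    participant_id: str
    measure: Measure
    week_index: int
    phase: Phase
    value: float | None = None


def validate_observation(
    obs: MeasureObservation,
    ranges: dict[Measure, tuple[float | None, float | None]] | None = None,
) -> None:
    ranges = DEFAULT_VALUE_RANGES if ranges is None else ranges
    if obs.week_index < 0:
        raise ValidationError(f"{obs.participant_id}: week_index must be >= 0")
    if obs.value is None:
        return
    if math.isnan(obs.value):
        raise ValidationError(
            f"{obs.participant_id}: NaN value; use an empty field for missing"
        )
    lo, hi = ranges.get(obs.measure, (None, None))
    if lo is not None and obs.value < lo or hi is not None and obs.value > hi:
        raise ValidationError(
            f"{obs.participant_id}: {obs.measure.value} value {obs.value} "
            f"outside [{lo}, {hi}]"
        )
    if obs.measure in _INTEGER_MEASURES and obs.value != int(obs.value):
        raise ValidationError(
            f"{obs.participant_id}: {obs.measure.value} must be an integer count"
        )


def _obs_sort_key(obs: MeasureObservation):
    return (obs.measure.value, obs.week_index, _PHASE_ORDER[obs.phase])


@dataclass
class ParticipantSeries:
    """All observations of one participant, kept sorted by (measure, week)."""

    participant_id: str
    dropout_status: Dropout = Dropout.COMPLETER
    observations: list[MeasureObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observations.sort(key=_obs_sort_key)

    def add(self, obs: MeasureObservation) -> None:
        self.observations.append(obs)
        self.observations.sort(key=_obs_sort_key)

    def assessment(self, measure: Measure, timepoint: Phase) -> float | None:
        """Value at an assessment timepoint (T0/T1/T2), or None."""
        if timepoint not in ASSESSMENT_PHASES:
            raise ValueError(f"{timepoint} is not an assessment phase")
        for obs in self.observations:
            if obs.measure is measure and obs.phase is timepoint:
                return obs.value
        return None


@dataclass
class StudyDataset:
    """Participants plus (optional) per-session records and design assignments.

    ``session_records`` maps participant id to a list of
    :class:`scedlab.vr_effect.SessionRecord`; ``design`` maps participant id
    to a :class:`scedlab.design.DesignAssignment`.
    """

    participants: list[ParticipantSeries] = field(default_factory=list)
    session_records: dict[str, list] = field(default_factory=dict)
    design: dict[str, object] = field(default_factory=dict)

    def participant(self, participant_id: str) -> ParticipantSeries:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]


def validate_dataset(
    dataset: StudyDataset,
    ranges: dict[Measure, tuple[float | None, float | None]] | None = None,
) -> None:
    """Raise :class:`ValidationError` on any violated invariant."""
    ids = dataset.participant_ids
    if len(set(ids)) != len(ids):
        raise ValidationError("participant ids are not unique")
    for series in dataset.participants:
        seen: set[tuple] = set()
        for obs in series.observations:
            if obs.participant_id != series.participant_id:
                raise ValidationError(
                    f"observation id {obs.participant_id} inside series "
                    f"{series.participant_id}"
                )
            validate_observation(obs, ranges)
            key = (obs.measure, obs.week_index, obs.phase)
            if key in seen:
                raise ValidationError(
                    f"{series.participant_id}: duplicate observation for {key}"
                )
            seen.add(key)
    known = set(ids)
    for pid in dataset.session_records:
        if pid not in known:
            raise ValidationError(f"session records for unknown participant {pid}")
    for pid in dataset.design:
        if pid not in known:
            raise ValidationError(f"design assignment for unknown participant {pid}")


def extract_phase(
    series: ParticipantSeries,
    measure: Measure,
    phases: Iterable[Phase],
) -> list[float]:
    """Non-missing values of ``measure`` in the given phases, by week order."""
    wanted = set(phases)
    picked = [
        obs
        for obs in series.observations
        if obs.measure is measure and obs.phase in wanted and obs.value is not None
    ]
    picked.sort(key=lambda o: o.week_index)
    return [o.value for o in picked]


_CSV_COLUMNS = ["participant_id", "measure", "week_index", "phase", "value"]


def read_long_csv(path: str | Path) -> StudyDataset:
    """Read a long-format observation table into a validated dataset.

    Blank ``value`` fields become missing observations (never zero).  An
    optional ``dropout_status`` column sets the participant status; absent,
    every participant is a completer.
    """
    path = Path(path)
    series: dict[str, ParticipantSeries] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_CSV_COLUMNS) <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: header must contain columns {', '.join(_CSV_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            pid = row["participant_id"].strip()
            try:
                measure = Measure(row["measure"].strip())
            except ValueError:
                raise ParseError(
                    f"{path} row {lineno}: unknown measure {row['measure']!r}"
                ) from None
            try:
                phase = Phase(row["phase"].strip())
            except ValueError:
                raise ParseError(
                    f"{path} row {lineno}: unknown phase {row['phase']!r}"
                ) from None
            try:
                week = int(row["week_index"])
            except ValueError:
                raise ParseError(
                    f"{path} row {lineno}: week_index {row['week_index']!r} "
                    "is not an integer"
                ) from None
            raw = (row["value"] or "").strip()
            value = float(raw) if raw else None
            obs = MeasureObservation(pid, measure, week, phase, value)
            if pid not in series:
                series[pid] = ParticipantSeries(pid)
            if "dropout_status" in row and (row["dropout_status"] or "").strip():
                series[pid].dropout_status = Dropout(row["dropout_status"].strip())
            series[pid].observations.append(obs)
    dataset = StudyDataset(participants=[ParticipantSeries(
        p.participant_id, p.dropout_status, p.observations) for p in series.values()])
    validate_dataset(dataset)
    return dataset


def write_long_csv(dataset: StudyDataset, path: str | Path) -> None:
    """Write observations in deterministic (participant, measure, week) order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS + ["dropout_status"])
        for series in sorted(dataset.participants, key=lambda s: s.participant_id):
            for obs in sorted(series.observations, key=_obs_sort_key):
                writer.writerow(
                    [
                        obs.participant_id,
                        obs.measure.value,
                        obs.week_index,
                        obs.phase.value,
                        "" if obs.value is None else _fmt_value(obs.value),
                        series.dropout_status.value,
                    ]
                )


def _fmt_value(value: float) -> str:
    return str(int(value)) if value == int(value) else repr(value)


def dataset_to_json(dataset: StudyDataset, path: str | Path | None = None) -> str:
    """Serialize the full dataset (observations, sessions, design) to JSON."""
    from .design import DesignAssignment  # local import to avoid a cycle
    from .vr_effect import SessionRecord

    payload = {
        "participants": [
            {
                "participant_id": s.participant_id,
                "dropout_status": s.dropout_status.value,
                "observations": [
                    {
                        "measure": o.measure.value,
                        "week_index": o.week_index,
                        "phase": o.phase.value,
                        "value": o.value,
                    }
                    for o in s.observations
                ],
            }
            for s in sorted(dataset.participants, key=lambda s: s.participant_id)
        ],
        "session_records": {
            pid: [asdict(r) for r in recs]
            for pid, recs in sorted(dataset.session_records.items())
        },
        "design": {
            pid: asdict(a) for pid, a in sorted(dataset.design.items())
        },
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def dataset_from_json(source: str | Path) -> StudyDataset:
    """Inverse of :func:`dataset_to_json` (accepts a path or a JSON string)."""
    from .design import DesignAssignment
    from .dpics import DPICSTally
    from .vr_effect import SessionRecord

    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    payload = json.loads(text)
    participants = []
    for p in payload.get("participants", []):
        series = ParticipantSeries(
            p["participant_id"], Dropout(p["dropout_status"]),
            [
                MeasureObservation(
                    p["participant_id"], Measure(o["measure"]),
                    int(o["week_index"]), Phase(o["phase"]), o["value"],
                )
                for o in p["observations"]
            ],
        )
        participants.append(series)
    sessions = {
        pid: [
            SessionRecord(
                participant_id=r["participant_id"],
                session_index=r["session_index"],
                tally=DPICSTally(**r["tally"]),
                vr_practices_since_previous=r["vr_practices_since_previous"],
            )
            for r in recs
        ]
        for pid, recs in payload.get("session_records", {}).items()
    }
    design = {
        pid: DesignAssignment(**a) for pid, a in payload.get("design", {}).items()
    }
    dataset = StudyDataset(participants, sessions, design)
    validate_dataset(dataset)
    return dataset
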