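"""The study's two randomizations and phase-schedule materialization.

Each participant is randomized twice at study start: to a baseline length of
4, 5 or 6 weekly measurements (the multiple-baseline stagger) and to the VR
add-on starting immediately, after 3 sessions, or after 6 sessions.  The
design is nonconcurrent: participants' calendars are independent and no
cross-participant stagger constraint is enforced.

Sessions are identified with weeks for scheduling (coaching is weekly); a
different session calendar can be expressed by rescaling
``n_intervention_weeks`` and ``addon_start`` before calling
:func:`phase_schedule`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import Phase

BASELINE_CHOICES = (4, 5, 6)
ADDON_CHOICES = (0, 3, 6)

#: Weekly follow-up measurements in phase C.
FOLLOWUP_MEASUREMENTS = 3

#: Default gap between intervention end and follow-up: 6 months.
DEFAULT_FOLLOWUP_GAP_WEEKS = 26


@dataclass(frozen=True)
class DesignAssignment:
    participant_id: str
    baseline_length: int  # weeks in phase A, one of {4, 5, 6}
    addon_start: int      # sessions after intervention start, one of {0, 3, 6}
    rng_seed: int

    def __post_init__(self) -> None:
        if self.baseline_length not in BASELINE_CHOICES:
            raise ValueError(f"baseline_length must be in {BASELINE_CHOICES}")
        if self.addon_start not in ADDON_CHOICES:
            raise ValueError(f"addon_start must be in {ADDON_CHOICES}")


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous, non-overlapping week ranges for phases A, B, B2 and C."""

    participant_id: str
    a_weeks: range
    b_weeks: range
    b2_weeks: range
    c_weeks: range
    addon_start_week: int

    def phase_of_week(self, week: int) -> Phase:
        for phase, weeks in (
            (Phase.A, self.a_weeks),
            (Phase.B, self.b_weeks),
            (Phase.B2, self.b2_weeks),
            (Phase.C, self.c_weeks),
        ):
            if week in weeks:
                return phase
        raise KeyError(f"week {week} is not a scheduled slot")

    @property
    def weekly_slots(self) -> list[tuple[int, Phase]]:
        slots = [(w, Phase.A) for w in self.a_weeks]
        slots += [(w, Phase.B) for w in self.b_weeks]
        slots += [(w, Phase.B2) for w in self.b2_weeks]
        slots += [(w, Phase.C) for w in self.c_weeks]
        return slots


def assign_design(
    participant_ids: Sequence[str],
    rng: np.random.Generator | int,
) -> list[DesignAssignment]:
    """Draw both randomizations independently and uniformly per participant.

    The two factors are drawn independently from {4,5,6} x {0,3,6}, so each
    of the nine design cells has probability 1/9.  Reproducible given a seed
    or a seeded generator; the seed recorded on each assignment is derived
    from the generator so exports are self-describing.
    """
    if not participant_ids:
        raise ValueError("participant_ids must be non-empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = len(participant_ids)
    baselines = rng.choice(BASELINE_CHOICES, size=n)
    addons = rng.choice(ADDON_CHOICES, size=n)
    seeds = rng.integers(0, 2**31, size=n)
    return [
        DesignAssignment(pid, int(b), int(a), int(s))
        for pid, b, a, s in zip(participant_ids, baselines, addons, seeds)
    ]


def phase_schedule(
    assignment: DesignAssignment,
    n_intervention_weeks: int,
    followup_gap_weeks: int = DEFAULT_FOLLOWUP_GAP_WEEKS,
) -> PhaseSchedule:
    """Materialize week ranges from an assignment.

    Phase A spans ``baseline_length`` weeks from week 0; phase B covers the
    intervention weeks before the add-on starts (empty when the add-on starts
    immediately); phase B2 the remainder of the intervention; phase C holds
    three weekly measurements starting ``followup_gap_weeks`` after the
    intervention ends.
    """
    if n_intervention_weeks < assignment.addon_start:
        raise ValueError(
            f"n_intervention_weeks ({n_intervention_weeks}) < addon_start "
            f"({assignment.addon_start})"
        )
    a_end = assignment.baseline_length
    addon_week = a_end + assignment.addon_start
    b2_end = a_end + n_intervention_weeks
    c_start = b2_end + followup_gap_weeks
    return PhaseSchedule(
        participant_id=assignment.participant_id,
        a_weeks=range(0, a_end),
        b_weeks=range(a_end, addon_week),
        b2_weeks=range(addon_week, b2_end),
        c_weeks=range(c_start, c_start + FOLLOWUP_MEASUREMENTS),
        addon_start_week=addon_week,
    )


def write_assignments_csv(assignments: Sequence[DesignAssignment],
                          path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "baseline_length", "addon_start", "seed"])
        for a in assignments:
            writer.writerow([a.participant_id, a.baseline_length,
                             a.addon_start, a.rng_seed])


def read_assignments_csv(path: str | Path) -> list[DesignAssignment]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [
            DesignAssignment(
                row["participant_id"],
                int(row["baseline_length"]),
                int(row["addon_start"]),
                int(row["seed"]),
            )
            for row in csv.DictReader(fh)
        ]
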