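"""Session-to-session skill differences conditioned on VR practice.

For every pair of adjacent archived sessions where the parent practiced
with VR in between, the change in the two DPICS composites is recorded:
positive following is first capped at 30 on each side (30 tallied skills is
the mastery amount — 10 labeled praises, 10 reflections, 10 behavior
descriptions — so anything above it carries no further signal), while
negative leading is uncapped.  Per-parent medians and means of those
differences form the session-effect table; parents are additionally split
into low/high VR-practice groups at a configured total-use cutoff
(default: 6 or fewer practices vs 7 or more).
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dpics import DPICSTally, negative_leading, positive_following

__all__ = [
    "SessionRecord",
    "VREffectConfig",
    "SessionDiff",
    "DiffSummary",
    "cap_positive",
    "session_diffs",
    "summarize_diffs",
    "split_by_use",
    "read_session_csv",
    "write_session_csv",
]


@dataclass(frozen=True)
class SessionRecord:
    """One archived session: its DPICS tally and VR use since the previous one."""

    participant_id: str
    session_index: int
    tally: DPICSTally
    vr_practices_since_previous: int = 0

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")
        if self.vr_practices_since_previous < 0:
            raise ValueError("vr_practices_since_previous must be >= 0")


@dataclass(frozen=True)
class VREffectConfig:
    positive_cap: int = 30    # mastery amount of tallied skills
    min_practices: int = 1    # VR practices needed for a pair to qualify
    group_split_cutoff: int = 6  # low group: total use <= cutoff

    def __post_init__(self) -> None:
        if self.positive_cap <= 0:
            raise ValueError("positive_cap must be positive")


@dataclass(frozen=True)
class SessionDiff:
    participant_id: str
    from_session: int
    to_session: int
    delta_pf_capped: int
    delta_nl: int


@dataclass(frozen=True)
class DiffSummary:
    n_pairs: int
    median_pf: float
    median_nl: float
    mean_pf: float
    mean_nl: float


def cap_positive(count: int, cap: int = 30) -> int:
    if count < 0:
        raise ValueError("count must be >= 0")
    return min(count, cap)


def session_diffs(
    records: Sequence[SessionRecord],
    config: VREffectConfig = VREffectConfig(),
    require_adjacent: bool = False,
) -> list[SessionDiff]:
    """Composite differences over qualifying consecutive session pairs.

    Records are the *archived* sessions in index order; adjacent records
    form a pair (``require_adjacent`` restricts to pairs whose session
    indices differ by exactly one, dropping pairs that straddle an
    unarchived session).  A pair qualifies when the later record logs at
    least ``config.min_practices`` VR practices since the previous one.
    """
    ordered = sorted(records, key=lambda r: r.session_index)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.session_index == nxt.session_index:
            raise ValueError(
                f"duplicate session_index {nxt.session_index} "
                f"for {nxt.participant_id}"
            )
    diffs = []
    for prev, nxt in zip(ordered, ordered[1:]):
        if require_adjacent and nxt.session_index != prev.session_index + 1:
            continue
        if nxt.vr_practices_since_previous < config.min_practices:
            continue
        pf_prev = cap_positive(positive_following(prev.tally), config.positive_cap)
        pf_next = cap_positive(positive_following(nxt.tally), config.positive_cap)
        diffs.append(
            SessionDiff(
                participant_id=nxt.participant_id,
                from_session=prev.session_index,
                to_session=nxt.session_index,
                delta_pf_capped=pf_next - pf_prev,
                delta_nl=negative_leading(nxt.tally) - negative_leading(prev.tally),
            )
        )
    return diffs


def summarize_diffs(diffs: Sequence[SessionDiff]) -> DiffSummary | None:
    """Median and mean of the PF and NL differences; None when no pair qualifies.

    Medians of even-length lists are the mean of the two middle values.
    """
    if not diffs:
        return None
    pf = [d.delta_pf_capped for d in diffs]
    nl = [d.delta_nl for d in diffs]
    return DiffSummary(
        n_pairs=len(diffs),
        median_pf=float(statistics.median(pf)),
        median_nl=float(statistics.median(nl)),
        mean_pf=float(statistics.fmean(pf)),
        mean_nl=float(statistics.fmean(nl)),
    )


def split_by_use(
    totals: Mapping[str, int],
    cutoff: int = 6,
) -> tuple[dict[str, int], dict[str, int]]:
    """Partition participants into low (total <= cutoff) and high (> cutoff)."""
    low, high = {}, {}
    for pid, total in totals.items():
        if total < 0:
            raise ValueError(f"negative VR total for {pid}")
        (low if total <= cutoff else high)[pid] = total
    return low, high


def diff_table(
    records_by_participant: Mapping[str, Sequence[SessionRecord]],
    config: VREffectConfig = VREffectConfig(),
) -> pd.DataFrame:
    """Session-effect table: one row per parent with any qualifying pair."""
    rows = []
    for pid in sorted(records_by_participant):
        summary = summarize_diffs(session_diffs(records_by_participant[pid], config))
        if summary is None:
            continue
        rows.append(
            {
                "participant_id": pid,
                "n_pairs": summary.n_pairs,
                "median_pf": summary.median_pf,
                "median_nl": summary.median_nl,
                "mean_pf": summary.mean_pf,
                "mean_nl": summary.mean_nl,
            }
        )
    return pd.DataFrame(rows)


_TALLY_FIELDS = (
    "labeled_praise", "unlabeled_praise", "reflection", "behavior_description",
    "question", "direct_command", "indirect_command", "negative_talk",
)


def write_session_csv(
    records_by_participant: Mapping[str, Sequence[SessionRecord]],
    path: str | Path,
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "session_index",
                         *_TALLY_FIELDS, "vr_practices_since_previous"])
        for pid in sorted(records_by_participant):
            for rec in sorted(records_by_participant[pid],
                              key=lambda r: r.session_index):
                writer.writerow(
                    [pid, rec.session_index]
                    + [getattr(rec.tally, f) for f in _TALLY_FIELDS]
                    + [rec.vr_practices_since_previous]
                )


def read_session_csv(path: str | Path) -> dict[str, list[SessionRecord]]:
    records: dict[str, list[SessionRecord]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row["participant_id"]
            rec = SessionRecord(
                participant_id=pid,
                session_index=int(row["session_index"]),
                tally=DPICSTally(**{f: int(row[f]) for f in _TALLY_FIELDS}),
                vr_practices_since_previous=int(row["vr_practices_since_previous"]),
            )
            records.setdefault(pid, []).append(rec)
    for recs in records.values():
        recs.sort(key=lambda r: r.session_index)
    return records
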