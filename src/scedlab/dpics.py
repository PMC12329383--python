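"""DPICS composites and mastery decisions.

The Dyadic Parent-Child Interaction Coding System tallies eight categories
of parent verbalizations in a 5-minute observation.  For the child-directed
phase these collapse into two composites:

* positive following = labeled praise + unlabeled praise + reflection +
  behavior description (the skills parents are coached to use);
* negative leading = question + direct command + indirect command +
  negative talk (the verbalizations parents are coached to avoid).

Mastery of the child-directed phase requires at least 10 labeled praises,
10 reflections and 10 behavior descriptions with zero questions, commands
or criticisms; criticism is carried by the negative-talk category.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class DPICSTally:
    """Non-negative category counts for one 5-minute observation."""

    labeled_praise: int = 0
    unlabeled_praise: int = 0
    reflection: int = 0
    behavior_description: int = 0
    question: int = 0
    direct_command: int = 0
    indirect_command: int = 0
    negative_talk: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"{f.name} must be a non-negative integer, got {v}")

    def __add__(self, other: "DPICSTally") -> "DPICSTally":
        """Concatenate observation windows (composites are additive)."""
        return DPICSTally(
            **{f.name: getattr(self, f.name) + getattr(other, f.name)
               for f in fields(self)}
        )


POSITIVE_CATEGORIES = (
    "labeled_praise", "unlabeled_praise", "reflection", "behavior_description",
)
NEGATIVE_CATEGORIES = (
    "question", "direct_command", "indirect_command", "negative_talk",
)


@dataclass(frozen=True)
class MasteryCriterion:
    min_labeled_praise: int = 10
    min_reflection: int = 10
    min_behavior_description: int = 10
    max_questions_commands_criticism: int = 0


def positive_following(tally: DPICSTally) -> int:
    return sum(getattr(tally, c) for c in POSITIVE_CATEGORIES)


def negative_leading(tally: DPICSTally) -> int:
    return sum(getattr(tally, c) for c in NEGATIVE_CATEGORIES)


def mastery_met(tally: DPICSTally,
                criterion: MasteryCriterion = MasteryCriterion()) -> bool:
    """True iff the skill minima are met with no disallowed verbalizations."""
    return (
        tally.labeled_praise >= criterion.min_labeled_praise
        and tally.reflection >= criterion.min_reflection
        and tally.behavior_description >= criterion.min_behavior_description
        and negative_leading(tally) <= criterion.max_questions_commands_criticism
    )


def coder_agreement(tally_a: DPICSTally, tally_b: DPICSTally) -> float:
    """Between-coder agreement for one observation, as a percentage.

    Per category the agreement is min/max of the two counts (1 when both are
    zero); the eight category agreements are averaged and scaled to [0, 100].
    This is a transparent count-ratio convention; interval-based or
    chance-corrected (kappa) statistics are deliberately out of scope.
    """
    ratios = []
    for name in POSITIVE_CATEGORIES + NEGATIVE_CATEGORIES:
        a, b = getattr(tally_a, name), getattr(tally_b, name)
        if a == 0 and b == 0:
            ratios.append(1.0)
        else:
            ratios.append(min(a, b) / max(a, b))
    return 100.0 * sum(ratios) / len(ratios)
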