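"""Synthetic multiple-baseline SCED datasets with the structure the analysis assumes.

The generator emulates the study conditions: around 11 families, most with
two participating parents (18 of 11 x 2 would be 22; the observed fraction
of two-parent families is 7/11), staggered baseline lengths of 4-6 weeks,
a VR add-on starting after 0/3/6 sessions, weekly ECBI Intensity
(range 36-252), ECBI Problem (0-36) and OBVL-K T-score series, per-session
DPICS tallies, VR practice counts from the add-on onward, missingness and
weekly dropout.

Weekly values follow a phase-level model with AR(1) Gaussian noise:

    y_t = mu(phase_t) + slope * t_intervention + e_t,
    e_t = rho * e_{t-1} + sqrt(1 - rho^2) * sigma * z_t,

clamped to the instrument range and rounded for count-like measures.  The
AR(1) term is the minimal serial-dependence model for weekly questionnaire
scores and lets tests document the randomization test's sensitivity to
autocorrelation.  Two parents of the same family share the child's ECBI
series (they rate the same child) but have independent OBVL and DPICS
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import (
    DEFAULT_VALUE_RANGES,
    Dropout,
    Measure,
    MeasureObservation,
    ParticipantSeries,
    Phase,
    StudyDataset,
)
from .design import DesignAssignment, assign_design, phase_schedule
from .dpics import DPICSTally
from .randomization import (
    Direction,
    PhaseComparison,
    cohens_d,
    randomization_p,
)
from .vr_effect import SessionRecord

__all__ = [
    "MeasureModel",
    "SimulationConfig",
    "simulate_participant",
    "simulate_dataset",
    "known_effect_recovery",
]


@dataclass(frozen=True)
class MeasureModel:
    """Phase-level generative model for one weekly measure."""

    baseline_mean: float
    within_sd: float
    b_effect: float = 0.0    # level change during phase B, raw units
    b2_effect: float = 0.0   # level change during phases B2 and C, raw units
    slope: float = 0.0       # weekly drift during the intervention
    integer: bool = False    # round to integer counts after noise

    def __post_init__(self) -> None:
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")


def _default_measures() -> dict[Measure, MeasureModel]:
    # Baseline levels follow the study conditions; within-person weekly SDs
    # and intervention effects are realistic stand-ins (documented in the
    # methods note) since no weekly dispersions are published.
    return {
        Measure.ECBI_INTENSITY: MeasureModel(150.0, 10.0, -15.0, -25.0, -0.5, True),
        Measure.ECBI_PROBLEM: MeasureModel(18.0, 2.5, -5.0, -8.0, -0.2, True),
        Measure.OBVL_K: MeasureModel(72.0, 4.0, -6.0, -10.0, -0.2, False),
        Measure.DPICS_PF: MeasureModel(4.0, 3.0, 10.0, 18.0, 1.0, True),
        Measure.DPICS_NL: MeasureModel(30.0, 6.0, -10.0, -15.0, -1.0, True),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 11
    prob_two_parent: float = 7.0 / 11.0
    n_intervention_weeks: int = 14
    followup_gap_weeks: int = 26
    measures: dict[Measure, MeasureModel] = field(default_factory=_default_measures)
    ar1_rho: float = 0.2
    missing_prob: float = 0.10
    dropout_hazard: float = 0.015      # per-week probability of dropping out
    keep_assessments_on_dropout: bool = True
    vr_rate: float = 0.8               # mean VR practices per add-on week

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for p in (self.prob_two_parent, self.missing_prob, self.dropout_hazard):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 <= self.ar1_rho <= 0.6:
            raise ValueError("ar1_rho must be in [0, 0.6]")
        if self.vr_rate < 0:
            raise ValueError("vr_rate must be >= 0")


def _ar1_noise(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    z = rng.standard_normal(n)
    e = np.empty(n)
    if n == 0:
        return e
    e[0] = sd * z[0]
    innov = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov * z[t]
    return e


def _clamp_round(values: np.ndarray, measure: Measure, model: MeasureModel) -> np.ndarray:
    lo, hi = DEFAULT_VALUE_RANGES.get(measure, (None, None))
    out = values.copy()
    if lo is not None:
        out = np.maximum(out, lo)
    if hi is not None:
        out = np.minimum(out, hi)
    if model.integer:
        out = np.rint(out)
    return out


def _weekly_series(
    model: MeasureModel,
    measure: Measure,
    schedule,
    rho: float,
    rng: np.random.Generator,
) -> list[tuple[int, Phase, float]]:
    slots = schedule.weekly_slots
    n = len(slots)
    means = np.empty(n)
    intervention_start = schedule.a_weeks.stop
    for i, (week, phase) in enumerate(slots):
        mu = model.baseline_mean
        if phase is Phase.B:
            mu += model.b_effect
        elif phase in (Phase.B2, Phase.C):
            mu += model.b2_effect
        if phase in (Phase.B, Phase.B2):
            mu += model.slope * (week - intervention_start)
        elif phase is Phase.C:
            mu += model.slope * (schedule.b2_weeks.stop - 1 - intervention_start)
        means[i] = mu
    values = _clamp_round(means + _ar1_noise(n, rho, model.within_sd, rng),
                          measure, model)
    return [(week, phase, float(v)) for (week, phase), v in zip(slots, values)]


def _session_tally(pf_target: float, nl_target: float,
                   rng: np.random.Generator) -> DPICSTally:
    # Split the composite targets across their four categories; labeled
    # praise / reflection / behavior description carry the mastery signal.
    pf_target = max(pf_target, 0.0)
    nl_target = max(nl_target, 0.0)
    pos = rng.poisson([pf_target * w for w in (0.3, 0.1, 0.3, 0.3)])
    neg = rng.poisson([nl_target * w for w in (0.4, 0.3, 0.2, 0.1)])
    return DPICSTally(
        labeled_praise=int(pos[0]), unlabeled_praise=int(pos[1]),
        reflection=int(pos[2]), behavior_description=int(pos[3]),
        question=int(neg[0]), direct_command=int(neg[1]),
        indirect_command=int(neg[2]), negative_talk=int(neg[3]),
    )


def simulate_participant(
    config: SimulationConfig,
    assignment: DesignAssignment,
    rng: np.random.Generator | int,
    shared_ecbi: dict[Measure, list[tuple[int, Phase, float]]] | None = None,
) -> tuple[ParticipantSeries, list[SessionRecord]]:
    """Simulate one participant under a design assignment.

    ``shared_ecbi`` lets a second parent of the same family reuse the
    child's ECBI weekly series.  VR counts are drawn only from the add-on
    start onward; missingness and dropout are applied after generation.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    schedule = phase_schedule(assignment, config.n_intervention_weeks,
                              config.followup_gap_weeks)
    pid = assignment.participant_id
    series_by_measure: dict[Measure, list[tuple[int, Phase, float]]] = {}
    for measure, model in config.measures.items():
        if shared_ecbi is not None and measure in (
            Measure.ECBI_INTENSITY, Measure.ECBI_PROBLEM
        ):
            series_by_measure[measure] = shared_ecbi[measure]
        else:
            series_by_measure[measure] = _weekly_series(
                model, measure, schedule, config.ar1_rho, rng
            )

    # Dropout: a per-week Bernoulli hazard over the scheduled weekly slots.
    all_weeks = sorted({w for slots in series_by_measure.values()
                        for w, _, _ in slots})
    dropout_week: int | None = None
    for week in all_weeks:
        if rng.random() < config.dropout_hazard:
            dropout_week = week
            break
    status = Dropout.COMPLETER
    if dropout_week is not None:
        status = (Dropout.DROPPED_INTERVENTION
                  if config.keep_assessments_on_dropout else Dropout.DROPPED_FULLY)

    observations: list[MeasureObservation] = []
    for measure, slots in series_by_measure.items():
        for week, phase, value in slots:
            if dropout_week is not None and week >= dropout_week:
                continue
            missing = rng.random() < config.missing_prob
            observations.append(
                MeasureObservation(pid, measure, week, phase,
                                   None if missing else value)
            )

    # Assessments at T0 (pre), T1 (post), T2 (follow-up): phase-level means
    # plus independent noise, on the same instruments.
    tp_phase_level = {Phase.T0: None, Phase.T1: Phase.B2, Phase.T2: Phase.C}
    include_assessments = (dropout_week is None
                           or config.keep_assessments_on_dropout)
    if include_assessments:
        for tp, level in tp_phase_level.items():
            for measure, model in config.measures.items():
                mu = model.baseline_mean
                if level is not None:
                    mu += model.b2_effect
                value = _clamp_round(
                    np.array([mu + rng.normal(0.0, model.within_sd)]),
                    measure, model,
                )[0]
                observations.append(
                    MeasureObservation(pid, measure, 0, tp, float(value))
                )

    # Weekly VR counts (B2 onward) and per-session DPICS tallies; sessions
    # are only generated when both DPICS composites are configured.
    pf_model = config.measures.get(Measure.DPICS_PF)
    nl_model = config.measures.get(Measure.DPICS_NL)
    if pf_model is None or nl_model is None:
        return ParticipantSeries(pid, status, observations), []
    session_records: list[SessionRecord] = []
    session_index = 0
    intervention_start = schedule.a_weeks.stop
    for week in list(schedule.b_weeks) + list(schedule.b2_weeks):
        if dropout_week is not None and week >= dropout_week:
            break
        session_index += 1
        in_addon = week >= schedule.addon_start_week
        vr_count = int(rng.poisson(config.vr_rate)) if in_addon else 0
        if in_addon:
            observations.append(
                MeasureObservation(pid, Measure.VR_COUNT, week, Phase.B2
                                   if week in schedule.b2_weeks else Phase.B,
                                   float(vr_count))
            )
        t = week - intervention_start
        pf_mu = pf_model.baseline_mean + pf_model.b2_effect * in_addon \
            + pf_model.b_effect * (not in_addon) + pf_model.slope * t
        nl_mu = nl_model.baseline_mean + nl_model.b2_effect * in_addon \
            + nl_model.b_effect * (not in_addon) + nl_model.slope * t
        session_records.append(
            SessionRecord(pid, session_index, _session_tally(pf_mu, nl_mu, rng),
                          vr_practices_since_previous=vr_count)
        )

    return ParticipantSeries(pid, status, observations), session_records


def simulate_dataset(
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> StudyDataset:
    """Simulate a full study: families expanded into one or two parents.

    Both parents of a two-parent family share the child's ECBI series but
    have independent OBVL and DPICS series and independent design draws are
    *not* made — the family shares one baseline/add-on assignment, as the
    staggering applies to the treatment calendar of the family.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(int(seed))
    pids: list[str] = []
    family_of: dict[str, int] = {}
    counter = 0
    for fam in range(config.n_families):
        n_parents = 2 if rng.random() < config.prob_two_parent else 1
        for _ in range(n_parents):
            counter += 1
            pid = f"{counter:02d}"
            pids.append(pid)
            family_of[pid] = fam

    assignments = assign_design(pids, rng)
    # One design per family: copy the first parent's draw to the second.
    by_family: dict[int, DesignAssignment] = {}
    fixed = []
    for a in assignments:
        fam = family_of[a.participant_id]
        if fam in by_family:
            base = by_family[fam]
            a = replace(base, participant_id=a.participant_id)
        else:
            by_family[fam] = a
        fixed.append(a)

    participants, sessions, design = [], {}, {}
    shared: dict[int, dict] = {}
    for a in fixed:
        fam = family_of[a.participant_id]
        reuse = shared.get(fam)
        series, recs = simulate_participant(config, a, rng, shared_ecbi=reuse)
        if reuse is None:
            shared[fam] = {
                m: [(o.week_index, o.phase, o.value)
                    for o in series.observations
                    if o.measure is m and o.phase not in
                    (Phase.T0, Phase.T1, Phase.T2) and o.value is not None]
                for m in (Measure.ECBI_INTENSITY, Measure.ECBI_PROBLEM)
            }
        participants.append(series)
        sessions[a.participant_id] = recs
        design[a.participant_id] = a
    return StudyDataset(participants, sessions, design)


def known_effect_recovery(
    delta: float,
    n_per_phase: int = 10,
    n_replicates: int = 500,
    within_sd: float = 10.0,
    rho: float = 0.0,
    alpha: float = 0.05,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Calibration harness: inject a level change and measure recovery.

    Simulates ``n_replicates`` two-phase series with a baseline mean of 0
    and an intervention mean of ``-delta`` (therapeutic decrease), runs the
    randomization test on each, and reports the mean recovered level change
    (baseline mean minus intervention mean), its Monte-Carlo SE, and the
    rejection rate at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_replicates)
    rejections = 0
    for i in range(n_replicates):
        noise = _ar1_noise(2 * n_per_phase, rho, within_sd, rng)
        baseline = noise[:n_per_phase]
        intervention = -delta + noise[n_per_phase:]
        estimates[i] = baseline.mean() - intervention.mean()
        comp = PhaseComparison(tuple(baseline), tuple(intervention),
                               Direction.DECREASE_IS_EFFECT)
        result = randomization_p(comp, n_resamples=n_resamples, rng=rng)
        if result.p <= alpha:
            rejections += 1
    return {
        "delta_true": delta,
        "delta_hat": float(estimates.mean()),
        "se": float(estimates.std(ddof=1) / np.sqrt(n_replicates)),
        "power": rejections / n_replicates,
        "n_replicates": n_replicates,
    }
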