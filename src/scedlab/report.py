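"""End-to-end analysis: assemble the study's result tables from a dataset.

Every cell in the report is the direct output of the underlying operation
(randomization test, RCI engine, contrast table, session-difference
summary); this layer only routes data and records metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import Dropout, Measure, Phase, StudyDataset, extract_phase
from .contrasts import contrast_table
from .randomization import (
    CombinationMethod,
    DegenerateVarianceError,
    Direction,
    PhaseComparison,
    Scheme,
    combine_p,
    effect_size_label,
    randomization_p,
)
from .reliable_change import DEFAULT_PARAMS, rci_summary, rci_table, results_frame
from .vr_effect import VREffectConfig, diff_table, split_by_use

logger = logging.getLogger(__name__)

#: Weekly measures entering the randomization table, with their
#: therapeutic direction.
RANDOMIZATION_MEASURES: dict[Measure, Direction] = {
    Measure.ECBI_INTENSITY: Direction.DECREASE_IS_EFFECT,
    Measure.OBVL_K: Direction.DECREASE_IS_EFFECT,
}


@dataclass(frozen=True)
class AnalysisConfig:
    n_resamples: int = 1000
    scheme: Scheme = Scheme.LABEL_PERMUTATION
    alpha: float = 0.05
    seed: int = 0
    baseline_phases: tuple[Phase, ...] = (Phase.A,)
    intervention_phases: tuple[Phase, ...] = (Phase.B, Phase.B2)
    vr: VREffectConfig = field(default_factory=VREffectConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        kwargs = dict(data)
        if "scheme" in kwargs:
            kwargs["scheme"] = Scheme(kwargs["scheme"])
        for key in ("baseline_phases", "intervention_phases"):
            if key in kwargs:
                kwargs[key] = tuple(Phase(p) for p in kwargs[key])
        if "vr" in kwargs:
            kwargs["vr"] = VREffectConfig(**kwargs["vr"])
        return cls(**kwargs)


@dataclass
class AnalysisReport:
    randomization: pd.DataFrame
    vr_diffs: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]
    raw_scores: pd.DataFrame
    rci: pd.DataFrame
    rci_counts: pd.DataFrame
    metadata: dict


def randomization_table(dataset: StudyDataset, config: AnalysisConfig) -> pd.DataFrame:
    """Per-participant randomization tests plus group combination rows.

    Participants lacking two measurement points in either phase are
    excluded with a logged reason.  Group rows combine the individual
    p-values with the exact uniform-sum CDF, for all tested participants
    and for treatment completers.
    """
    rows = []
    ps: dict[Measure, dict[str, float]] = {m: {} for m in RANDOMIZATION_MEASURES}
    completers: set[str] = set()
    for series in dataset.participants:
        if series.dropout_status is Dropout.COMPLETER:
            completers.add(series.participant_id)
        for measure, direction in RANDOMIZATION_MEASURES.items():
            baseline = extract_phase(series, measure, config.baseline_phases)
            intervention = extract_phase(series, measure, config.intervention_phases)
            comp = PhaseComparison(tuple(baseline), tuple(intervention), direction)
            if not comp.meets_inclusion_rule:
                logger.info(
                    "excluded %s / %s from the randomization table: "
                    "fewer than 2 points in a phase (baseline %d, intervention %d)",
                    series.participant_id, measure.value,
                    len(baseline), len(intervention),
                )
                continue
            try:
                result = randomization_p(
                    comp, config.n_resamples, config.scheme,
                    rng=_participant_seed(config.seed, series.participant_id),
                )
            except DegenerateVarianceError:
                logger.info(
                    "excluded %s / %s: constant series, effect size undefined",
                    series.participant_id, measure.value,
                )
                continue
            ps[measure][series.participant_id] = result.p
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "measure": measure.value,
                    "d": result.d_obs,
                    "effect_label": effect_size_label(result.d_obs),
                    "p": result.p,
                    "scheme": result.scheme.value,
                    "n_resamples": result.n_resamples,
                }
            )
    for measure in RANDOMIZATION_MEASURES:
        groups = {
            "all_tested": list(ps[measure].values()),
            "completers": [p for pid, p in ps[measure].items() if pid in completers],
        }
        for name, values in groups.items():
            if not values:
                continue
            combo = combine_p(values, CombinationMethod.IRWIN_HALL_EXACT)
            rows.append(
                {
                    "participant_id": f"group:{name}",
                    "measure": measure.value,
                    "d": None,
                    "effect_label": "",
                    "p": combo.group_p,
                    "scheme": "irwin_hall_exact",
                    "n_resamples": len(values),
                }
            )
    return pd.DataFrame(rows)


def _participant_seed(seed: int, participant_id: str) -> int:
    return (seed * 100003 + hash(participant_id) % 99991) % (2**31)


def raw_score_table(dataset: StudyDataset,
                    split_cutoff: int = 6) -> pd.DataFrame:
    """Assessment raw scores per participant with the VR-use group split."""
    totals = {}
    for series in dataset.participants:
        vr = extract_phase(series, Measure.VR_COUNT,
                           (Phase.A, Phase.B, Phase.B2, Phase.C))
        totals[series.participant_id] = int(sum(vr))
    low, high = split_by_use(totals, split_cutoff)
    rows = []
    for series in dataset.participants:
        pid = series.participant_id
        row = {
            "participant_id": pid,
            "vr_total": totals[pid],
            "vr_group": "low" if pid in low else "high",
            "dropout_status": series.dropout_status.value,
        }
        for measure in (Measure.DPICS_PF, Measure.DPICS_NL,
                        Measure.ECBI_INTENSITY, Measure.ECBI_PROBLEM,
                        Measure.OBVL_K):
            for tp in (Phase.T0, Phase.T1, Phase.T2):
                row[f"{measure.value}_{tp.value}"] = series.assessment(measure, tp)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze(dataset: StudyDataset,
            config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full analysis pipeline on a validated dataset."""
    config = config or AnalysisConfig()
    rand = randomization_table(dataset, config)
    vr = diff_table(dataset.session_records, config.vr)
    contrasts = {
        m.value: contrast_table(dataset, m)
        for m in (Measure.DPICS_PF, Measure.DPICS_NL)
    }
    rci_results = rci_table(dataset, DEFAULT_PARAMS)
    report = AnalysisReport(
        randomization=rand,
        vr_diffs=vr,
        contrasts=contrasts,
        raw_scores=raw_score_table(dataset, config.vr.group_split_cutoff),
        rci=results_frame(rci_results),
        rci_counts=rci_summary(rci_results),
        metadata={
            "version": __version__,
            "seed": config.seed,
            "n_resamples": config.n_resamples,
            "scheme": config.scheme.value,
            "alpha": config.alpha,
        },
    )
    if rand.empty:
        raise ValueError("no analyzable participant in the dataset")
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.randomization.to_csv(out / "randomization.csv", index=False)
    report.vr_diffs.to_csv(out / "vr_session_diffs.csv", index=False)
    for name, table in report.contrasts.items():
        table.to_csv(out / f"contrasts_{name}.csv", index=False)
        table.attrs["contrasts"].to_csv(
            out / f"contrasts_{name}_pairs.csv", index=False
        )
    report.raw_scores.to_csv(out / "raw_scores.csv", index=False)
    report.rci.to_csv(out / "rci.csv", index=False)
    report.rci_counts.to_csv(out / "rci_counts.csv", index=False)
    bundle = {
        "metadata": report.metadata,
        "randomization": report.randomization.to_dict(orient="records"),
        "vr_session_diffs": report.vr_diffs.to_dict(orient="records"),
        "rci_counts": report.rci_counts.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(bundle, indent=2),
                                     encoding="utf-8")


def plot_data(dataset: StudyDataset, out_dir: str | Path) -> list[Path]:
    """Export per-participant series files with phase markers and bands.

    One JSON file per participant per weekly measure, containing the series
    with phase labels, the week indices of the A|B, B|B2 and B2|C phase
    boundaries, the add-on start marker (absent when the participant has no
    B2 weeks) and, for the DPICS composites, the visual-inspection
    reference bands (positive following good above 30, negative leading
    good below 5).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    bands = {
        Measure.DPICS_PF: {"good_above": 30},
        Measure.DPICS_NL: {"good_below": 5},
    }
    weekly = (Measure.ECBI_INTENSITY, Measure.ECBI_PROBLEM, Measure.OBVL_K,
              Measure.DPICS_PF, Measure.DPICS_NL)
    for series in dataset.participants:
        for measure in weekly:
            rows = [
                {"week": o.week_index, "phase": o.phase.value, "value": o.value}
                for o in series.observations
                if o.measure is measure and o.phase in
                (Phase.A, Phase.B, Phase.B2, Phase.C)
            ]
            if not rows:
                continue
            markers = _phase_markers(rows)
            payload = {
                "participant_id": series.participant_id,
                "measure": measure.value,
                "series": rows,
                "markers": markers,
            }
            if measure in bands:
                payload["bands"] = bands[measure]
            path = out / f"{series.participant_id}_{measure.value}.json"
            path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
            written.append(path)
    return written


def _phase_markers(rows: list[dict]) -> dict:
    first_week = {}
    for row in rows:
        phase = row["phase"]
        if phase not in first_week or row["week"] < first_week[phase]:
            first_week[phase] = row["week"]
    markers = {}
    if "B" in first_week:
        markers["baseline_end"] = first_week["B"]
    elif "B2" in first_week:
        markers["baseline_end"] = first_week["B2"]
    if "B2" in first_week:
        markers["addon_start"] = first_week["B2"]
    if "C" in first_week:
        markers["followup_start"] = first_week["C"]
    return markers
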