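"""End-to-end orchestration: session -> z-traces -> trials -> metrics -> coupling.

These helpers wire the module chain together in the fixed order the analysis
defines (preprocess -> align -> QC -> metrics -> pairing) and are what the CLI
and the acceptance script call.  They operate on in-memory sessions; the io
module handles disk round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignedTrial, AlignmentSpec, apply_qc, extract_trials
from .config import AnalysisConfig
from .coupling import CouplingPoint, fit_coupling, pair_looming, pair_social
from .metrics import TrialMetrics, compute_trial_metrics
from .preprocess import preprocess_recording
from .synth import ASTRO_SENSOR, NEURON_SENSOR, SyntheticSession


@dataclass
class SessionResult:
    """Everything the pipeline computed for one session."""

    paradigm: str
    ztraces: dict
    included: dict[str, list[AlignedTrial]]
    excluded: dict[str, list[AlignedTrial]]
    metrics: dict[str, list[TrialMetrics]]
    points: list[CouplingPoint] = field(default_factory=list)


def spec_for(paradigm: str, config: AnalysisConfig | None = None) -> AlignmentSpec:
    config = config or AnalysisConfig()
    if paradigm == "social":
        return AlignmentSpec.social(
            min_bout_s=config.min_bout_s,
            min_events_per_subject=config.min_events_per_subject,
            baseline_irregularity_z=config.baseline_irregularity_z,
            max_trials_per_subject=config.max_trials_per_subject,
            irregularity_mode=config.irregularity_mode,
        )
    return AlignmentSpec.looming(
        baseline_irregularity_z=config.baseline_irregularity_z,
        irregularity_mode=config.irregularity_mode,
    )


def analyze_session(
    session: SyntheticSession,
    config: AnalysisConfig | None = None,
    apply_trial_qc: bool = True,
) -> SessionResult:
    """Run the full chain on one session (synthetic or loaded from disk)."""
    config = config or AnalysisConfig()
    paradigm = session.truth.paradigm if session.truth is not None else "social"
    spec = spec_for(paradigm, config)
    ztraces = preprocess_recording(session.recording, config)
    included: dict[str, list[AlignedTrial]] = {}
    excluded: dict[str, list[AlignedTrial]] = {}
    metrics: dict[str, list[TrialMetrics]] = {}
    frac = (
        config.ignore_fraction_social
        if paradigm == "social"
        else config.ignore_fraction_looming
    )
    for sensor, zt in ztraces.items():
        trials = extract_trials(zt, session.events, spec)
        if apply_trial_qc:
            inc, exc = apply_qc(trials, spec)
        else:
            inc, exc = [t for t in trials if t.included], [
                t for t in trials if not t.included
            ]
        included[sensor] = inc
        excluded[sensor] = exc
        metrics[sensor] = [
            compute_trial_metrics(tr, paradigm, ignore_fraction=frac,
                                  baseline_window=spec.baseline_window)
            for tr in inc
        ]
    points = pair_session(included, metrics, paradigm, spec)
    return SessionResult(
        paradigm=paradigm,
        ztraces=ztraces,
        included=included,
        excluded=excluded,
        metrics=metrics,
        points=points,
    )


def pair_session(
    included: dict[str, list[AlignedTrial]],
    metrics: dict[str, list[TrialMetrics]],
    paradigm: str,
    spec: AlignmentSpec,
) -> list[CouplingPoint]:
    """Pair neuron/astro trials of the same event that both passed QC."""
    neuron = {t.trial_idx: t for t in included.get(NEURON_SENSOR, [])}
    astro = {t.trial_idx: t for t in included.get(ASTRO_SENSOR, [])}
    nmetrics = {m.trial_idx: m for m in metrics.get(NEURON_SENSOR, [])}
    points: list[CouplingPoint] = []
    for idx in sorted(set(neuron) & set(astro)):
        if paradigm == "social":
            pt = pair_social(neuron[idx], nmetrics[idx], astro[idx])
        else:
            pt = pair_looming(neuron[idx], astro[idx],
                              baseline_window=spec.baseline_window)
        if pt is not None:
            points.append(pt)
    return points


def fit_pooled_coupling(results: list[SessionResult], condition: str = ""):
    points = [p for r in results for p in r.points]
    return fit_coupling(points, condition=condition), points


def pooled_metrics_frame(results: list[SessionResult]) -> pd.DataFrame:
    from .metrics import metrics_to_frame

    frames = [
        metrics_to_frame(ms) for r in results for ms in r.metrics.values() if ms
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def epoch_matrix(results: list[SessionResult], sensor: str) -> np.ndarray:
    """(n_trials, 3) baseline/loom/post epoch means for the RM ANOVA."""
    rows = []
    for r in results:
        for m in r.metrics.get(sensor, []):
            if m.epoch_means:
                rows.append(
                    [m.epoch_means["baseline"], m.epoch_means["loom"],
                     m.epoch_means["post"]]
                )
    return np.array(rows) if rows else np.empty((0, 3))
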