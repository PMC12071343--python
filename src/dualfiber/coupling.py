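"""Neuron-astrocyte functional coupling: trial pairing and linear regression.

Per trial, a single delta-z coordinate is taken from each simultaneously
recorded sensor and the points are pooled within a condition (sex x
familiarity for social sessions, sex x response for looming).  Two pairing
modes mirror the published analysis:

* peak-anchored (social): x = the neuron sensor's peak delta-z; y = the
  astrocyte sensor's delta-z sampled at the neuron's time of peak
  (nearest-sample lookup — both sensors share one acquisition clock);
* epoch-mean (looming): each coordinate = mean z over 5-8 s minus the mean
  over the -5..0 s baseline for its own sensor.

The coupling fit is ordinary least squares of y on x with slope, intercept,
R^2 and the two-sided p-value for slope != 0 (t distribution, n-2 df).
Trials are pooled across animals without a subject random effect, matching
the published per-trial scatter; a hierarchical model is a noted non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .align import AlignedTrial
from .metrics import TrialMetrics, LOOM_EPOCH


@dataclass
class CouplingPoint:
    neuron_dz: float
    astro_dz: float
    subject_id: str
    trial_idx: int
    pairing_mode: str
    labels: dict


@dataclass
class CouplingFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    condition: str = ""


def pair_social(
    neuron_trial: AlignedTrial,
    neuron_metrics: TrialMetrics,
    astro_trial: AlignedTrial,
) -> CouplingPoint | None:
    """Peak-anchored pairing; returns None when the neuron trial has no peak."""
    if neuron_metrics.peak_dz is None or neuron_metrics.t_peak is None:
        return None
    if neuron_trial.rel_time.size != astro_trial.rel_time.size:
        raise ValueError("neuron and astrocyte trials must share one rel_time grid")
    i = int(np.argmin(np.abs(astro_trial.rel_time - neuron_metrics.t_peak)))
    return CouplingPoint(
        neuron_dz=float(neuron_metrics.peak_dz),
        astro_dz=float(astro_trial.dz[i]),
        subject_id=neuron_trial.subject_id,
        trial_idx=neuron_trial.trial_idx,
        pairing_mode="peak_anchored",
        labels=dict(neuron_trial.labels),
    )


def pair_looming(
    neuron_trial: AlignedTrial,
    astro_trial: AlignedTrial,
    baseline_window: tuple[float, float] = (-5.0, 0.0),
) -> CouplingPoint | None:
    """Epoch-mean pairing: mean z over 5-8 s minus baseline mean, per sensor."""

    def coord(tr: AlignedTrial) -> float | None:
        t = tr.rel_time
        loom = (t >= LOOM_EPOCH[0]) & (t <= LOOM_EPOCH[1])
        base = (t >= baseline_window[0]) & (t <= baseline_window[1])
        if not loom.any() or not base.any():
            return None
        return float(np.mean(tr.dz[loom]) - np.mean(tr.dz[base]))

    x, y = coord(neuron_trial), coord(astro_trial)
    if x is None or y is None:
        return None
    return CouplingPoint(
        neuron_dz=x,
        astro_dz=y,
        subject_id=neuron_trial.subject_id,
        trial_idx=neuron_trial.trial_idx,
        pairing_mode="epoch_mean",
        labels=dict(neuron_trial.labels),
    )


def fit_coupling(points: list[CouplingPoint], condition: str = "") -> CouplingFit:
    """OLS of astrocyte delta-z on neuron delta-z over the pooled points."""
    if len(points) < 3:
        raise ValueError(f"need >= 3 points for a coupling fit, got {len(points)}")
    x = np.array([p.neuron_dz for p in points])
    y = np.array([p.astro_dz for p in points])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor (all neuron delta-z equal)")
    res = sstats.linregress(x, y)
    return CouplingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(points),
        condition=condition,
    )


def points_to_frame(points: list[CouplingPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in points],
            "trial_idx": [p.trial_idx for p in points],
            "pairing_mode": [p.pairing_mode for p in points],
            "neuron_dz": [p.neuron_dz for p in points],
            "astro_dz": [p.astro_dz for p in points],
            "sex": [p.labels.get("sex", "n/a") for p in points],
            "familiarity": [p.labels.get("familiarity", "n/a") for p in points],
            "response_category": [
                p.labels.get("response_category", "n/a") for p in points
            ],
        }
    )
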