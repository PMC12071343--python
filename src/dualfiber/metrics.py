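"""Per-trial transient metrics: curve selection, peak, AUC, epoch means.

A "curve" is a maximal contiguous run of samples on one side of zero, bounded
by zero crossings — the unit the published AUC analysis operates on.  For
social trials the curve containing sniff initiation (t = 0) is selected; for
looming trials the curve with maximal overlap with the 5-8 s full-expansion
period (ties broken to the earlier region).  Peaks are local maxima inside
the selected curve; a peak whose height above the trial minimum is less than
``ignore_fraction`` of the trial's min-to-max range is ignored (5% for
social, 10% for looming; the range is taken over the whole trial window,
matching the graphing convention of the original analysis tool).  AUC is the
signed trapezoidal integral of delta-z over the curve, in z*s.

Looming epoch means average delta-z over the 5-8 s (shadow in full expansion)
and strictly-after-8-to-15 s (poststimulus) windows; the published "8.01 s"
start is read as "first sample strictly after 8 s" at any sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .align import AlignedTrial

LOOM_EPOCH = (5.0, 8.0)
POST_EPOCH = (8.0, 15.0)   # half-open at the left edge

IGNORE_FRACTION = {"social": 0.05, "looming": 0.10}


@dataclass
class TrialMetrics:
    subject_id: str
    sensor_id: str
    trial_idx: int
    peak_dz: float | None
    t_peak: float | None
    auc: float | None
    epoch_means: dict[str, float]
    curve_region: tuple[float, float] | None
    labels: dict


def find_curves(dz: np.ndarray) -> list[tuple[int, int]]:
    """Maximal same-sign runs as half-open index ranges [i0, i1).

    Samples exactly equal to zero separate curves and belong to none.
    """
    sign = np.sign(dz)
    curves: list[tuple[int, int]] = []
    start = None
    cur = 0.0
    for i, s in enumerate(sign):
        if s == 0 or s != cur:
            if start is not None and cur != 0:
                curves.append((start, i))
            start = i if s != 0 else None
            cur = s
    if start is not None and cur != 0:
        curves.append((start, sign.size))
    return curves


def select_curve(trial: AlignedTrial, paradigm: str) -> tuple[int, int] | None:
    """Pick the analysis curve for one trial; None flags "no_curve"."""
    curves = find_curves(trial.dz)
    if not curves:
        return None
    if paradigm == "social":
        # curve containing the first sample at or after t = 0
        i_zero = int(np.searchsorted(trial.rel_time, 0.0))
        for i0, i1 in curves:
            if i0 <= i_zero < i1:
                return (i0, i1)
        return None
    if paradigm == "looming":
        best, best_overlap = None, 0.0
        for i0, i1 in curves:
            t0, t1 = trial.rel_time[i0], trial.rel_time[i1 - 1]
            overlap = max(0.0, min(t1, LOOM_EPOCH[1]) - max(t0, LOOM_EPOCH[0]))
            if overlap > best_overlap:  # strict: ties keep the earlier region
                best, best_overlap = (i0, i1), overlap
        return best
    raise ValueError(f"unknown paradigm '{paradigm}'")


def detect_peak(
    trial: AlignedTrial,
    curve_region: tuple[int, int] | None,
    ignore_fraction: float,
) -> tuple[float, float] | None:
    """Highest surviving local maximum inside the curve; ties go to the earliest.

    A candidate is ignored when its height above the trial's minimum delta-z is
    below ``ignore_fraction`` times the trial's full min-to-max range.
    Returns (peak_dz, t_peak) or None when no peak survives.
    """
    if curve_region is None:
        return None
    i0, i1 = curve_region
    seg = trial.dz[i0:i1]
    if seg.size < 3:
        return None
    trial_min = float(np.min(trial.dz))
    trial_range = float(np.max(trial.dz) - trial_min)
    idx, _ = find_peaks(seg)
    if idx.size == 0:
        return None
    heights = seg[idx]
    keep = (heights - trial_min) >= ignore_fraction * trial_range
    if not keep.any():
        return None
    idx, heights = idx[keep], heights[keep]
    best = idx[int(np.argmax(heights))]  # argmax returns the earliest maximal entry
    return float(seg[best]), float(trial.rel_time[i0 + best])


def compute_auc(trial: AlignedTrial, curve_region: tuple[int, int] | None):
    """Signed trapezoidal integral of delta-z over the curve region (z*s)."""
    if curve_region is None:
        return None
    i0, i1 = curve_region
    if i1 - i0 < 2:
        return None
    return float(np.trapezoid(trial.dz[i0:i1], trial.rel_time[i0:i1]))


def epoch_means(
    trial: AlignedTrial, baseline_window: tuple[float, float] = (-5.0, 0.0)
) -> dict[str, float]:
    """Mean delta-z over baseline, looming (5-8 s closed) and poststimulus
    ((8, 15] s, i.e. strictly after the shadow disappears) epochs."""
    t = trial.rel_time
    if t[-1] < POST_EPOCH[1] - 1e-9:
        raise ValueError(
            f"trial window ends at {t[-1]:.2f} s; epochs need coverage to "
            f"{POST_EPOCH[1]} s"
        )
    masks = {
        "baseline": (t >= baseline_window[0]) & (t <= baseline_window[1]),
        "loom": (t >= LOOM_EPOCH[0]) & (t <= LOOM_EPOCH[1]),
        "post": (t > POST_EPOCH[0]) & (t <= POST_EPOCH[1]),
    }
    return {k: float(np.mean(trial.dz[m])) for k, m in masks.items()}


def compute_trial_metrics(
    trial: AlignedTrial,
    paradigm: str,
    ignore_fraction: float | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> TrialMetrics:
    frac = IGNORE_FRACTION[paradigm] if ignore_fraction is None else ignore_fraction
    region = select_curve(trial, paradigm)
    peak = detect_peak(trial, region, frac)
    auc = compute_auc(trial, region)
    epochs: dict[str, float] = {}
    if paradigm == "looming":
        epochs = epoch_means(trial, baseline_window or (-5.0, 0.0))
    bounds = None
    if region is not None:
        bounds = (float(trial.rel_time[region[0]]), float(trial.rel_time[region[1] - 1]))
    return TrialMetrics(
        subject_id=trial.subject_id,
        sensor_id=trial.sensor_id,
        trial_idx=trial.trial_idx,
        peak_dz=None if peak is None else peak[0],
        t_peak=None if peak is None else peak[1],
        auc=auc,
        epoch_means=epochs,
        curve_region=bounds,
        labels=dict(trial.labels),
    )


def metrics_to_frame(metrics: list[TrialMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(
            {
                "subject_id": m.subject_id,
                "sensor_id": m.sensor_id,
                "trial_idx": m.trial_idx,
                "sex": m.labels.get("sex", "n/a"),
                "familiarity": m.labels.get("familiarity", "n/a"),
                "response_category": m.labels.get("response_category", "n/a"),
                "peak_dz": m.peak_dz,
                "t_peak_s": m.t_peak,
                "auc": m.auc,
                "mean_baseline": m.epoch_means.get("baseline"),
                "mean_5_8": m.epoch_means.get("loom"),
                "mean_post": m.epoch_means.get("post"),
                "curve_start_s": None if m.curve_region is None else m.curve_region[0],
                "curve_end_s": None if m.curve_region is None else m.curve_region[1],
            }
        )
    return pd.DataFrame(rows)
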