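"""Event-locked trial extraction, per-trial baseline subtraction, and QC.

Trials are cut from the z-scored trace around each anchoring behavioral event
(sniff initiation for social sessions, disc appearance for looming sessions),
the mean of a pre-event baseline window is subtracted from the whole segment
(giving the delta-z series), and the published inclusion rules are applied:

* social sniff bouts shorter than 1 s are discarded;
* subjects with a total qualifying-event count of 3 or fewer are excluded;
* trials whose baseline deviates from its own mean by more than 0.2 z at any
  sample are excluded ("beyond +/-0.2" is exclusive: a deviation of exactly
  0.2 passes);
* at most five trials per subject and condition are kept (chronologically
  first, a deterministic and bias-transparent reading of "up to five").

Exclusion reasons are evaluated in that order, so every excluded trial carries
exactly one machine-readable primary reason.  QC never raises on content and
is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import ZTrace

QC_INCLUDED = "included"
REASON_ORDER = ("min_bout", "min_events", "baseline_irregularity", "trial_cap")

ANCHOR_EVENT = {"social": "sniff", "looming": "loom_stimulus"}


@dataclass(frozen=True)
class AlignmentSpec:
    """Extraction windows and QC thresholds for one paradigm."""

    paradigm: str
    extract_window: tuple[float, float]
    baseline_window: tuple[float, float]
    min_bout_s: float | None = None
    min_events_per_subject: int | None = None
    baseline_irregularity_z: float = 0.2
    max_trials_per_subject: int | None = None
    irregularity_mode: str = "any_sample"  # or "window_mean"

    def __post_init__(self):
        t0, t1 = self.extract_window
        b0, b1 = self.baseline_window
        if not (t0 < 0 < t1):
            raise ValueError(f"extract window {self.extract_window} must straddle 0")
        if not (t0 <= b0 < b1 <= t1):
            raise ValueError(
                f"baseline window {self.baseline_window} must lie inside "
                f"extract window {self.extract_window}"
            )

    @classmethod
    def social(cls, **overrides) -> "AlignmentSpec":
        """Sniff-aligned: extract -8..5 s, baseline -8..-3 s, published QC."""
        kw = dict(
            paradigm="social",
            extract_window=(-8.0, 5.0),
            baseline_window=(-8.0, -3.0),
            min_bout_s=1.0,
            min_events_per_subject=4,
            baseline_irregularity_z=0.2,
            max_trials_per_subject=5,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def looming(cls, **overrides) -> "AlignmentSpec":
        """Stimulus-aligned: extract -5..15 s, baseline -5..0 s."""
        kw = dict(
            paradigm="looming",
            extract_window=(-5.0, 15.0),
            baseline_window=(-5.0, 0.0),
            baseline_irregularity_z=0.2,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class AlignedTrial:
    """One event-locked, baseline-subtracted segment of one sensor."""

    subject_id: str
    sensor_id: str
    event_type: str
    trial_idx: int
    onset_s: float
    bout_duration_s: float
    rel_time: np.ndarray
    dz: np.ndarray
    labels: dict = field(default_factory=dict)
    qc_status: str = QC_INCLUDED

    @property
    def included(self) -> bool:
        return self.qc_status == QC_INCLUDED

    def baseline_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.rel_time >= window[0]) & (self.rel_time <= window[1])


def extract_trials(
    ztrace: ZTrace, events: pd.DataFrame, spec: AlignmentSpec
) -> list[AlignedTrial]:
    """Cut one trial per anchoring event; baseline-subtract each segment.

    Events whose window would run past either end of the recording are kept
    but marked ``excluded:window_out_of_range``.  An empty event table gives
    an empty list.
    """
    anchor = ANCHOR_EVENT[spec.paradigm]
    rows = events[events["event_type"] == anchor].sort_values("start_s")
    fs = ztrace.sampling_rate
    t0 = float(ztrace.time[0])
    n = ztrace.z.size
    # fixed-length relative grid shared by all trials
    i_lo = int(round(spec.extract_window[0] * fs))
    i_hi = int(round(spec.extract_window[1] * fs))
    rel_time = np.arange(i_lo, i_hi + 1) / fs

    trials: list[AlignedTrial] = []
    for trial_idx, (_, row) in enumerate(rows.iterrows()):
        onset = float(row["start_s"])
        labels = {
            "sex": row.get("sex", "n/a"),
            "familiarity": row.get("familiarity", "n/a"),
            "response_category": row.get("response_category", "n/a"),
        }
        i_onset = int(round((onset - t0) * fs))
        lo, hi = i_onset + i_lo, i_onset + i_hi
        if lo < 0 or hi >= n:
            seg = np.full(rel_time.size, np.nan)
            trial = AlignedTrial(
                subject_id=ztrace.subject_id,
                sensor_id=ztrace.sensor_id,
                event_type=anchor,
                trial_idx=trial_idx,
                onset_s=onset,
                bout_duration_s=float(row["stop_s"] - row["start_s"]),
                rel_time=rel_time,
                dz=seg,
                labels=labels,
                qc_status="excluded:window_out_of_range",
            )
            trials.append(trial)
            continue
        seg = ztrace.z[lo : hi + 1].astype(float)
        bmask = (rel_time >= spec.baseline_window[0]) & (
            rel_time <= spec.baseline_window[1]
        )
        dz = seg - float(np.mean(seg[bmask]))
        trials.append(
            AlignedTrial(
                subject_id=ztrace.subject_id,
                sensor_id=ztrace.sensor_id,
                event_type=anchor,
                trial_idx=trial_idx,
                onset_s=onset,
                bout_duration_s=float(row["stop_s"] - row["start_s"]),
                rel_time=rel_time,
                dz=dz,
                labels=labels,
            )
        )
    return trials


def _condition_key(trial: AlignedTrial) -> tuple:
    if trial.event_type == "sniff":
        return (trial.labels.get("familiarity", "n/a"),)
    return (trial.labels.get("response_category", "n/a"),)


def apply_qc(
    trials: list[AlignedTrial], spec: AlignmentSpec
) -> tuple[list[AlignedTrial], list[AlignedTrial]]:
    """Apply the inclusion rules; returns (included, excluded-with-reasons).

    Trials already excluded upstream (e.g. window out of range) keep their
    reason; re-application is a no-op (QC is idempotent).
    """
    out: list[AlignedTrial] = []
    candidates: list[AlignedTrial] = []
    for tr in trials:
        if not tr.included:
            out.append(tr)
        else:
            candidates.append(tr)

    # rule 1: minimum bout duration (social)
    survivors: list[AlignedTrial] = []
    for tr in candidates:
        if spec.min_bout_s is not None and tr.bout_duration_s < spec.min_bout_s:
            out.append(replace(tr, qc_status="excluded:min_bout"))
        else:
            survivors.append(tr)

    # rule 2: subjects with too few qualifying events
    if spec.min_events_per_subject is not None:
        counts: dict[str, int] = {}
        for tr in survivors:
            counts[tr.subject_id] = counts.get(tr.subject_id, 0) + 1
        kept = []
        for tr in survivors:
            if counts[tr.subject_id] < spec.min_events_per_subject:
                out.append(replace(tr, qc_status="excluded:min_events"))
            else:
                kept.append(tr)
        survivors = kept

    # rule 3: baseline irregularity beyond +/- threshold (exclusive boundary)
    thr = spec.baseline_irregularity_z
    kept = []
    for tr in survivors:
        bseg = tr.dz[tr.baseline_mask(spec.baseline_window)]
        if spec.irregularity_mode == "window_mean":
            dev = abs(float(np.mean(bseg)))
        else:
            dev = float(np.max(np.abs(bseg - np.mean(bseg))))
        if dev > thr:
            out.append(replace(tr, qc_status="excluded:baseline_irregularity"))
        else:
            kept.append(tr)
    survivors = kept

    # rule 4: chronological trial cap per subject x condition
    if spec.max_trials_per_subject is not None:
        taken: dict[tuple, int] = {}
        kept = []
        for tr in sorted(survivors, key=lambda t: t.onset_s):
            key = (tr.subject_id, *_condition_key(tr))
            taken[key] = taken.get(key, 0) + 1
            if taken[key] > spec.max_trials_per_subject:
                out.append(replace(tr, qc_status="excluded:trial_cap"))
            else:
                kept.append(tr)
        survivors = kept

    included = sorted(survivors, key=lambda t: (t.subject_id, t.onset_s))
    excluded = [t for t in out if not t.included]
    # anything that arrived included and survived all rules stays included
    return included, excluded


def trials_to_frame(trials: list[AlignedTrial]) -> pd.DataFrame:
    """Long-format export (subject, sensor, trial, rel_time_s, dz, qc_status, labels)."""
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "sensor_id": tr.sensor_id,
                    "trial_idx": tr.trial_idx,
                    "rel_time_s": tr.rel_time,
                    "dz": tr.dz,
                    "qc_status": tr.qc_status,
                    "sex": tr.labels.get("sex", "n/a"),
                    "familiarity": tr.labels.get("familiarity", "n/a"),
                    "response_category": tr.labels.get("response_category", "n/a"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "subject_id", "sensor_id", "trial_idx", "rel_time_s", "dz",
                "qc_status", "sex", "familiarity", "response_category",
            ]
        )
    return pd.concat(frames, ignore_index=True)
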