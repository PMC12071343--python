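"""Scored-behavior summaries and looming-response classification.

Social sessions are summarized per subject and condition (total sniff time,
bout count, mean bout length; the bout-length comparison uses per-bout values,
matching the published per-bout degrees of freedom).  Looming stimuli are
classified into run / freeze / no-response: the first scored run or freeze
whose onset falls within [0, 8) s of disc appearance defines the category and
latency (the earlier behavior wins when both occur); anything later counts as
no response.  Latency is measured from disc appearance, the same t = 0 used
for signal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RESPONSE_WINDOW_S = 8.0
CATEGORIES = ("run", "freeze", "none")


@dataclass
class LoomingResponse:
    trial_id: int
    category: str
    latency_s: float | None
    freeze_duration_s: float | None
    sex: str = "n/a"
    subject_id: str = "n/a"


def summarize_sniffs(events: pd.DataFrame) -> pd.DataFrame:
    """Per subject x familiarity: total sniff seconds, bout count, mean bout length.

    Expects post-QC sniff events (the >=1 s rule is applied upstream).  A
    subject/condition with no bouts reports total 0, n 0 and a missing mean.
    """
    sniffs = events[events["event_type"] == "sniff"].copy()
    sniffs["bout_s"] = sniffs["stop_s"] - sniffs["start_s"]
    grouped = (
        sniffs.groupby(["subject_id", "sex", "familiarity"], dropna=False)["bout_s"]
        .agg(total_sniff_s="sum", n_bouts="count", mean_bout_s="mean")
        .reset_index()
    )
    return grouped


def sniff_bout_table(events: pd.DataFrame) -> pd.DataFrame:
    """Long per-bout table (one row per bout) for the bout-length comparison."""
    sniffs = events[events["event_type"] == "sniff"].copy()
    sniffs["bout_s"] = sniffs["stop_s"] - sniffs["start_s"]
    return sniffs[["subject_id", "sex", "familiarity", "bout_s"]].reset_index(drop=True)


def classify_looming(
    events: pd.DataFrame, stimulus_onsets: np.ndarray | list[float]
) -> list[LoomingResponse]:
    """One response category per stimulus from the scored run/freeze intervals.

    Raises when consecutive stimuli are closer than the 8 s response window
    (responses could not be attributed unambiguously).
    """
    onsets = np.sort(np.asarray(stimulus_onsets, dtype=float))
    if onsets.size >= 2 and np.min(np.diff(onsets)) < RESPONSE_WINDOW_S:
        raise ValueError(
            "stimulus onsets closer than the 8 s response window: "
            f"{np.min(np.diff(onsets)):.2f} s apart"
        )
    scored = events[events["event_type"].isin(["run", "freeze"])]
    scored = scored.sort_values("start_s")
    responses: list[LoomingResponse] = []
    for k, onset in enumerate(onsets):
        next_onset = onsets[k + 1] if k + 1 < onsets.size else np.inf
        in_window = scored[
            (scored["start_s"] >= onset)
            & (scored["start_s"] < onset + RESPONSE_WINDOW_S)
        ]
        meta = events[events["event_type"] == "loom_stimulus"]
        meta_row = meta[np.isclose(meta["start_s"], onset)]
        sex = meta_row["sex"].iloc[0] if len(meta_row) else "n/a"
        subject = meta_row["subject_id"].iloc[0] if len(meta_row) else "n/a"
        if len(in_window) == 0:
            responses.append(
                LoomingResponse(k, "none", None, None, sex=sex, subject_id=subject)
            )
            continue
        first = in_window.iloc[0]  # earliest onset wins when run and freeze co-occur
        category = first["event_type"]
        latency = float(first["start_s"] - onset)
        freeze_duration = None
        if category == "freeze":
            # all scored freeze time attributable to this stimulus
            fr = scored[
                (scored["event_type"] == "freeze")
                & (scored["start_s"] >= onset)
                & (scored["start_s"] < next_onset)
            ]
            freeze_duration = float((fr["stop_s"] - fr["start_s"]).sum())
        responses.append(
            LoomingResponse(k, category, latency, freeze_duration, sex=sex,
                            subject_id=subject)
        )
    return responses


def response_counts(responses: list[LoomingResponse]) -> pd.DataFrame:
    """2 x 3 count table (rows = sex, columns = run/freeze/none)."""
    rows = pd.DataFrame(
        {"sex": [r.sex for r in responses], "category": [r.category for r in responses]}
    )
    table = (
        rows.groupby(["sex", "category"]).size().unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
    )
    table.columns.name = None
    return table


def response_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentage of trials per category within each sex (rows sum to 100)."""
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a sex group has zero trials; cannot form percentages")
    return 100.0 * counts.div(counts.sum(axis=1), axis=0)


def proportions_from_responses(responses: list[LoomingResponse]) -> pd.DataFrame:
    if not responses:
        raise ValueError("need at least one classified response")
    return response_proportions(response_counts(responses))
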