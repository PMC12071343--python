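"""Reading, writing and validation of photometry recordings and behavioral event tables.

The on-disk dialect is deliberately plain: comma-separated UTF-8 with a header
row, time in seconds as float, one column per fluorescence channel.  No vendor
standard exists for photometry exports, so a documented in-house dialect plus a
column-mapping config is the most portable choice.  Event tables follow the
shape of a BORIS export (subject, event type, start/stop in seconds, plus the
group labels the analysis needs).

All readers *reject* malformed input rather than silently repairing it; error
messages name the offending column or rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical channel layout: sensor id -> (signal column, isosbestic column)
DEFAULT_SENSORS: dict[str, tuple[str, str]] = {
    "gcamp6f": ("sig_fast", "iso_fast"),
    "rcamp2": ("sig_slow", "iso_slow"),
}

RECORDING_COLUMNS = ["time_s", "sig_fast", "iso_fast", "sig_slow", "iso_slow"]

EVENT_COLUMNS = [
    "subject_id",
    "event_type",
    "start_s",
    "stop_s",
    "sex",
    "familiarity",
    "response_category",
    "latency_s",
]

EVENT_TYPES = {"sniff", "loom_stimulus", "run", "freeze"}

#: relative tolerance on the sampling interval before a time base counts as non-uniform
TIME_UNIFORMITY_RTOL = 1e-6


class RecordingError(ValueError):
    """Raised when a recording violates its invariants."""


class EventTableError(ValueError):
    """Raised when an event table violates its invariants."""


@dataclass
class RawRecording:
    """A multichannel fluorescence recording with channel roles.

    Parameters
    ----------
    time
        Session time in seconds, strictly increasing and uniform, 0 = first sample.
    channels
        Mapping channel id -> fluorescence series (arbitrary units).
    sensors
        Mapping sensor id -> (signal channel id, isosbestic channel id).  Every
        signal channel must have exactly one isosbestic partner.
    subject_id, sex
        Subject metadata carried through to trials.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sensors: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_SENSORS)
    )
    subject_id: str = "subject0"
    sex: str = "n/a"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        validate_recording(self)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sampling_rate


def validate_recording(rec: RawRecording) -> None:
    if rec.time.ndim != 1 or rec.time.size < 3:
        raise RecordingError("time column must be 1-D with at least 3 samples")
    dt = np.diff(rec.time)
    if np.any(dt <= 0):
        raise RecordingError("column 'time_s': time base is not strictly increasing")
    dt0 = np.median(dt)
    if np.max(np.abs(dt - dt0)) > TIME_UNIFORMITY_RTOL * dt0:
        raise RecordingError(
            "column 'time_s': non-uniform sampling interval "
            f"(max deviation {np.max(np.abs(dt - dt0)):.3g} s vs step {dt0:.3g} s)"
        )
    for name, series in rec.channels.items():
        if series.shape != rec.time.shape:
            raise RecordingError(
                f"column '{name}': length {series.size} != time length {rec.time.size}"
            )
        if np.any(~np.isfinite(series)):
            raise RecordingError(f"column '{name}': contains non-finite values")
    for sensor, (sig, iso) in rec.sensors.items():
        if sig not in rec.channels:
            raise RecordingError(f"sensor '{sensor}': missing signal column '{sig}'")
        if iso not in rec.channels:
            raise RecordingError(
                f"sensor '{sensor}': unpaired channel '{sig}' "
                f"(isosbestic partner column '{iso}' not found)"
            )


def read_recording(
    path,
    sensors: dict[str, tuple[str, str]] | None = None,
    column_map: dict[str, str] | None = None,
    subject_id: str = "subject0",
    sex: str = "n/a",
) -> RawRecording:
    """Read a recording CSV (columns ``time_s`` + one per channel).

    ``column_map`` renames vendor column names onto the canonical ones before
    validation, e.g. ``{"AIn-1": "sig_fast"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "time_s" not in df.columns:
        raise RecordingError(f"{path}: required column 'time_s' is missing")
    sensors = dict(sensors or DEFAULT_SENSORS)
    channel_cols = [c for c in df.columns if c != "time_s"]
    for col in channel_cols:
        if df[col].isna().any():
            raise RecordingError(f"{path}: column '{col}' contains missing values")
    channels = {c: df[c].to_numpy(dtype=float) for c in channel_cols}
    return RawRecording(
        time=df["time_s"].to_numpy(dtype=float),
        channels=channels,
        sensors=sensors,
        subject_id=subject_id,
        sex=sex,
    )


def write_recording(rec: RawRecording, path) -> None:
    cols = {"time_s": rec.time}
    cols.update(rec.channels)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"event table missing required column(s): {missing}")
    bad_type = ~df["event_type"].isin(EVENT_TYPES)
    if bad_type.any():
        rows = df.index[bad_type].tolist()
        raise EventTableError(
            f"column 'event_type': unknown value(s) in rows {rows}: "
            f"{sorted(df.loc[bad_type, 'event_type'].unique())}"
        )
    bad = df["stop_s"] < df["start_s"]
    if bad.any():
        rows = df.index[bad].tolist()
        raise EventTableError(f"column 'stop_s' < 'start_s' in rows {rows}")
    return df.reset_index(drop=True)


def make_event_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate an event table from row dicts; fills label defaults."""
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in EVENT_COLUMNS})
    df = pd.DataFrame(rows)
    for col, default in (
        ("sex", "n/a"),
        ("familiarity", "n/a"),
        ("response_category", "n/a"),
        ("latency_s", np.nan),
    ):
        if col not in df.columns:
            df[col] = default
    return validate_events(df[EVENT_COLUMNS])


def read_events(path) -> pd.DataFrame:
    """Read and validate a behavioral event table CSV."""
    return validate_events(pd.read_csv(path))


def write_events(df: pd.DataFrame, path) -> None:
    validate_events(df).to_csv(path, index=False)


def check_events_within(df: pd.DataFrame, rec: RawRecording) -> None:
    """Reject events lying outside the recording's time span."""
    t0, t1 = float(rec.time[0]), float(rec.time[-1])
    bad = (df["start_s"] < t0) | (df["stop_s"] > t1)
    if bad.any():
        raise EventTableError(
            f"events outside recording span [{t0}, {t1}]: rows {df.index[bad].tolist()}"
        )
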