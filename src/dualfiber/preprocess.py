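"""The photometry signal path: detrend -> isosbestic subtraction -> low-pass -> z-score.

Each raw channel is first baseline-corrected with a least-squares polynomial
fit over the whole session (photobleaching is slow and smooth, so a low-order
polynomial captures it without eating multi-second calcium transients).  Motion
artifacts are then removed by subtracting the calcium-insensitive isosbestic
channel from its paired signal channel at each time point; because both
channels travel the same fiber, mechanical artifacts appear in both with the
same waveform and cancel.  A zero-phase low-pass (second-order Butterworth run
forward and backward) at 0.3 Hz removes residual high-frequency noise without
shifting event timing, which the time-of-peak analyses require.  Finally the
trace is z-scored as z = (F - F0) / sigma_F, with F0 and sigma_F the mean and
standard deviation of the basal signal (by default the entire corrected
session; a restricted basal window is configurable).

Every stage is a pure function: identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as sps

from .config import AnalysisConfig
from .io import RawRecording


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BasalStats:
    """Mean and SD of the basal signal used for z-scoring."""

    f0: float
    sigma_f: float
    basal_window: tuple[float, float]

    def __post_init__(self):
        if not self.sigma_f > 0:
            raise PreprocessError(
                f"zero variance in basal window {self.basal_window}: cannot z-score"
            )


@dataclass
class ZTrace:
    """A motion-corrected, filtered, z-scored single-sensor trace."""

    time: np.ndarray
    z: np.ndarray
    sensor_id: str
    basal_stats: BasalStats
    poly_order: int
    cutoff_hz: float
    subject_id: str = "subject0"
    sex: str = "n/a"

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


def detrend_baseline(trace: np.ndarray, time: np.ndarray, order: int):
    """Subtract a least-squares polynomial of the given order fit to the whole trace.

    Returns ``(residual, fitted_curve)``; the fitted curve is returned for
    inspection.  Fitting is done on a rescaled time axis for conditioning.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if order < 0:
        raise PreprocessError(f"polynomial order must be >= 0, got {order}")
    if trace.size <= order + 1:
        raise PreprocessError(
            f"trace length {trace.size} too short for polynomial order {order}"
        )
    # map time to [-1, 1] so high orders stay well-conditioned
    tmid = 0.5 * (time[0] + time[-1])
    thalf = 0.5 * (time[-1] - time[0])
    x = (time - tmid) / thalf
    coef = npoly.polyfit(x, trace, order)
    fitted = npoly.polyval(x, coef)
    return trace - fitted, fitted


def motion_correct(
    signal_trace: np.ndarray, isosbestic_trace: np.ndarray, rescale: bool = False
) -> np.ndarray:
    """Remove shared motion artifacts using the isosbestic control channel.

    Default is the plain pointwise difference signal - isosbestic.  With
    ``rescale=True`` the isosbestic trace is first scaled by its OLS fit to the
    signal, for rigs where the two channels have unequal artifact gain.
    """
    s = np.asarray(signal_trace, dtype=float)
    i = np.asarray(isosbestic_trace, dtype=float)
    if s.shape != i.shape:
        raise PreprocessError(
            f"signal length {s.size} != isosbestic length {i.size}"
        )
    if rescale:
        denom = float(np.dot(i, i))
        beta = float(np.dot(i, s)) / denom if denom > 0 else 0.0
        return s - beta * i
    return s - i


def butter_lowpass(cutoff_hz: float, fs: float):
    nyq = fs / 2.0
    if not cutoff_hz < nyq:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz at fs={fs})"
        )
    return sps.butter(2, cutoff_hz / nyq)


def lowpass(trace: np.ndarray, fs: float, cutoff_hz: float = 0.3) -> np.ndarray:
    """Zero-phase low-pass (Butterworth order 2, forward-backward). DC gain 1.

    Edges use Gustafsson's method (initial conditions chosen so the forward
    and backward passes agree), which avoids the large boundary transients
    reflect-padding produces at cutoffs far below the sampling rate.
    """
    trace = np.asarray(trace, dtype=float)
    b, a = butter_lowpass(cutoff_hz, fs)
    irlen = int(min(trace.size - 1, round(10 * fs / cutoff_hz)))
    return sps.filtfilt(b, a, trace, method="gust", irlen=irlen)


def zscore(
    trace: np.ndarray,
    time: np.ndarray,
    basal_window: tuple[float, float] | None = None,
    sensor_id: str = "sensor",
    poly_order: int = 2,
    cutoff_hz: float = 0.3,
    subject_id: str = "subject0",
    sex: str = "n/a",
) -> ZTrace:
    """z = (F - F0)/sigma_F with basal statistics from ``basal_window``.

    ``basal_window=None`` uses the entire trace as the basal signal.
    """
    trace = np.asarray(trace, dtype=float)
    time = np.asarray(time, dtype=float)
    if basal_window is None:
        window = (float(time[0]), float(time[-1]))
        basal = trace
    else:
        window = (float(basal_window[0]), float(basal_window[1]))
        mask = (time >= window[0]) & (time <= window[1])
        if not mask.any():
            raise PreprocessError(f"basal window {window} contains no samples")
        basal = trace[mask]
    f0 = float(np.mean(basal))
    sigma = float(np.std(basal))
    stats = BasalStats(f0=f0, sigma_f=sigma, basal_window=window)
    return ZTrace(
        time=time,
        z=(trace - f0) / sigma,
        sensor_id=sensor_id,
        basal_stats=stats,
        poly_order=poly_order,
        cutoff_hz=cutoff_hz,
        subject_id=subject_id,
        sex=sex,
    )


def decimate_recording(rec: RawRecording, target_hz: float) -> RawRecording:
    """Anti-aliased integer-factor decimation of every channel."""
    fs = rec.sampling_rate
    factor = int(round(fs / target_hz))
    if factor <= 1:
        return rec
    channels = {
        name: sps.decimate(series, factor, zero_phase=True)
        for name, series in rec.channels.items()
    }
    return RawRecording(
        time=rec.time[::factor][: next(iter(channels.values())).size],
        channels=channels,
        sensors=rec.sensors,
        subject_id=rec.subject_id,
        sex=rec.sex,
    )


def preprocess_recording(
    rec: RawRecording, config: AnalysisConfig | None = None
) -> dict[str, ZTrace]:
    """Run the full signal path on every sensor of a recording.

    Pipeline order is fixed: detrend each channel, subtract the detrended
    isosbestic from its paired signal channel, low-pass, z-score.
    """
    config = config or AnalysisConfig()
    if rec.sampling_rate > config.decimate_to_hz * (1 + 1e-9):
        rec = decimate_recording(rec, config.decimate_to_hz)
    fs = rec.sampling_rate
    out: dict[str, ZTrace] = {}
    for sensor, (sig_col, iso_col) in rec.sensors.items():
        sig, _ = detrend_baseline(rec.channels[sig_col], rec.time, config.poly_order)
        iso, _ = detrend_baseline(rec.channels[iso_col], rec.time, config.poly_order)
        corrected = motion_correct(sig, iso, rescale=config.isosbestic_rescale)
        filtered = lowpass(corrected, fs, config.filter_cutoff_hz)
        out[sensor] = zscore(
            filtered,
            rec.time,
            basal_window=config.basal_window,
            sensor_id=sensor,
            poly_order=config.poly_order,
            cutoff_hz=config.filter_cutoff_hz,
            subject_id=rec.subject_id,
            sex=rec.sex,
        )
    return out
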