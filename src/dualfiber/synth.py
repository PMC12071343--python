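"""Ground-truth-parameterized synthetic dual-sensor photometry sessions.

The generator emulates a dual-color recording of a fast green sensor
(GCaMP6f-like, astrocytes) and a slow red sensor (RCaMP2-like, neurons), each
with a calcium-insensitive isosbestic control channel:

* slow photobleaching drift (double-exponential, channel-specific);
* motion artifacts injected with the *same* waveform into the signal and
  isosbestic channels, so isosbestic subtraction cancels them;
* event-locked calcium transients: peak-normalized difference-of-exponential
  kernels with sensor-specific rise/decay time constants, so the kernel
  amplitude equals the true peak;
* basal activity that dominates session variance — sparse spontaneous
  transients placed *between* analysis windows plus a slow basal wander
  (session-period sinusoids) — mimicking real photometry, where ongoing
  population activity rather than detector noise sets the basal SD;
* white Gaussian noise, independent per channel.

True event amplitudes are specified in delta-z units.  Because the analysis
z-scores by the whole-session basal SD of the *processed* trace, the
generator converts amplitudes to raw fluorescence with a deterministic
calibration: a small internal replica of the analysis signal path
(polynomial detrend + zero-phase Butterworth; written against scipy/numpy
primitives directly, independent of the analysis module) predicts the basal
SD of the noiseless session, the analytic noise bandwidth of the filter adds
the noise term, and the known filter attenuation of each kernel
pre-compensates the peak.  The astrocyte amplitude is further calibrated so
that the astrocyte delta-z sampled at the neuron's time of peak equals
``coupling_slope * A + coupling_intercept + noise`` — i.e. the coupling
parameters describe exactly the peak-anchored pairing the analysis measures.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as sps

from .io import RawRecording, make_event_table

NEURON_SENSOR = "rcamp2"   # slow red sensor, OXT neurons, x-axis of coupling
ASTRO_SENSOR = "gcamp6f"   # fast green sensor, astrocytes, y-axis

#: looming stimulus phases (s): small disc, expansion, full-size hold
LOOM_PHASES = (3.0, 2.0, 3.0)
LOOM_DURATION_S = sum(LOOM_PHASES)
MIN_LOOM_SPACING_S = 60.0

#: analysis windows the generator must keep clear of spontaneous activity
WINDOW_BY_PARADIGM = {"social": (-8.0, 5.0), "looming": (-5.0, 15.0)}

DEFAULT_KINETICS = {ASTRO_SENSOR: (0.1, 0.6), NEURON_SENSOR: (0.3, 1.5)}

#: pooled looming response-category probabilities (run, freeze, none)
DEFAULT_RESPONSE_PROBS = {"run": 48 / 84, "freeze": 20 / 84, "none": 16 / 84}


def _default_bleach():
    # (amplitude a.u., time constant s) pairs; ~1-2% of the channel offset,
    # consistent with LED powers chosen for limited photobleaching
    return {
        "sig_fast": ((0.030, 60.0), (0.015, 400.0)),
        "iso_fast": ((0.020, 60.0), (0.010, 400.0)),
        "sig_slow": ((0.025, 60.0), (0.012, 400.0)),
        "iso_slow": ((0.018, 60.0), (0.009, 400.0)),
    }


def _default_motion():
    return [(97.0, 0.8, 0.12), (251.0, 0.5, -0.10), (404.0, 1.2, 0.15)]


@dataclass
class SimulationTruth:
    """All ground-truth parameters of one synthetic session."""

    paradigm: str = "social"
    sampling_rate: float = 100.0
    duration: float = 600.0
    channel_offsets: dict = field(
        default_factory=lambda: {
            "sig_fast": 2.0, "iso_fast": 1.2, "sig_slow": 1.8, "iso_slow": 1.0,
        }
    )
    bleach_params: dict = field(default_factory=_default_bleach)
    motion: list = field(default_factory=_default_motion)
    noise_sd: float = 0.006
    transient_kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    event_schedule: list = field(default_factory=list)  # (onset, offset, label)
    event_amplitudes: np.ndarray | None = None          # neuron true peak dz
    coupling_slope: float = 0.6
    coupling_intercept: float = 0.0
    coupling_noise_sd: float = 0.05
    # basal-activity world (sets sigma_F; see module docstring)
    wander_sd: float = 0.007          # per-sinusoid raw amplitude
    wander_periods: tuple = (600.0, 300.0)
    spontaneous_rate: float = 0.18    # events/s within allowed gaps
    spontaneous_amp: float = 0.06     # raw kernel amplitude
    # QC-test hook: (time_s, duration_s, amplitude_z, sensor_id)
    baseline_glitches: list = field(default_factory=list)
    # looming-only
    response_labels: list | None = None      # per-stimulus category
    response_latencies: list | None = None
    response_gain: dict = field(
        default_factory=lambda: {"run": 1.0, "freeze": 0.6, "none": 0.0}
    )
    loom_transient_onset_s: float = 4.5  # relative to disc appearance (expansion phase)
    # analysis settings the z-unit calibration is defined against
    analysis_poly_order: int = 2
    analysis_cutoff_hz: float = 0.3
    subject_id: str = "subject0"
    sex: str = "female"
    familiarity: str = "unfamiliar"
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        for sensor, (rise, decay) in self.transient_kinetics.items():
            if rise <= 0 or decay <= 0:
                raise ValueError(f"sensor '{sensor}': time constants must be > 0")
            if decay <= rise:
                raise ValueError(f"sensor '{sensor}': decay must exceed rise")
        onsets = [ev[0] for ev in self.event_schedule]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for onset, offset, _ in self.event_schedule:
            if onset < 0 or offset > self.duration:
                raise ValueError(
                    f"event ({onset}, {offset}) does not fit in duration "
                    f"{self.duration}"
                )
        support = self.kernel_support_s()
        gaps = np.diff(onsets)
        if gaps.size and np.min(gaps) < support:
            raise ValueError(
                f"overlapping events: inter-onset gap {np.min(gaps):.2f} s is "
                f"shorter than the kernel support ({support:.2f} s)"
            )

    def kernel_support_s(self) -> float:
        return max(r + 5 * d for r, d in self.transient_kinetics.values())

    # -- factories -----------------------------------------------------------

    @classmethod
    def social(
        cls,
        rng_seed: int = 0,
        n_events: int = 10,
        duration: float = 600.0,
        min_spacing_s: float = 30.0,
        bout_range_s: tuple[float, float] = (1.2, 3.5),
        amp_range_z: tuple[float, float] = (0.15, 0.5),
        include_short_bouts: int = 0,
        **overrides,
    ) -> "SimulationTruth":
        """A 10-min home-cage interaction session with sniff bouts.

        Bout density is far below real scoring (~30/10 min) because the
        generator rejects events closer than the kernel support; see docs.
        ``include_short_bouts`` appends that many sub-1-s bouts (QC fodder).
        """
        rng = np.random.default_rng([rng_seed, 101])
        total = n_events + include_short_bouts
        lo = 25.0
        hi = duration - 25.0
        slots = np.linspace(lo, hi, total) if total > 1 else np.array([duration / 2])
        jitter = min(min_spacing_s, (hi - lo) / max(total - 1, 1) - min_spacing_s)
        onsets = np.sort(slots + rng.uniform(-max(jitter, 0) / 2,
                                             max(jitter, 0) / 2, total))
        durations = rng.uniform(*bout_range_s, total)
        short_idx = rng.choice(total, size=include_short_bouts, replace=False)
        durations[short_idx] = rng.uniform(0.4, 0.9, include_short_bouts)
        schedule = [
            (float(o), float(o + d), "sniff") for o, d in zip(onsets, durations)
        ]
        amps = rng.uniform(*amp_range_z, total)
        truth = cls(
            paradigm="social",
            duration=duration,
            event_schedule=schedule,
            event_amplitudes=amps,
            rng_seed=rng_seed,
            **overrides,
        )
        truth.validate()
        return truth

    @classmethod
    def looming(
        cls,
        rng_seed: int = 0,
        n_stimuli: int = 7,
        duration: float = 600.0,
        amp_range_z: tuple[float, float] = (0.2, 0.6),
        **overrides,
    ) -> "SimulationTruth":
        """A 10-min looming-shadow session: 6-8 stimuli, >= 60 s apart."""
        if not 6 <= n_stimuli <= 8:
            raise ValueError(f"stimulus count must be 6-8, got {n_stimuli}")
        rng = np.random.default_rng([rng_seed, 202])
        lo, hi = 20.0, duration - 25.0
        span = hi - lo
        if span < (n_stimuli - 1) * MIN_LOOM_SPACING_S:
            raise ValueError(
                f"{n_stimuli} stimuli with >= {MIN_LOOM_SPACING_S:.0f} s spacing "
                f"do not fit in {duration:.0f} s"
            )
        # jitter budget that preserves both the spacing and the margins
        slack = max(0.0, min((span - MIN_LOOM_SPACING_S * (n_stimuli - 1))
                             / n_stimuli, 20.0))
        base = np.linspace(lo + slack / 2, hi - slack / 2, n_stimuli)
        onsets = np.sort(base + rng.uniform(-slack / 2, slack / 2, n_stimuli))
        schedule = [
            (float(o), float(o + LOOM_DURATION_S), "loom_stimulus") for o in onsets
        ]
        cats = list(DEFAULT_RESPONSE_PROBS)
        probs = np.array([DEFAULT_RESPONSE_PROBS[c] for c in cats])
        labels = [cats[i] for i in rng.choice(len(cats), size=n_stimuli, p=probs)]
        latencies = []
        for lab in labels:
            if lab == "run":
                latencies.append(float(np.clip(rng.normal(4.3, 0.9), 1.0, 7.9)))
            elif lab == "freeze":
                latencies.append(float(np.clip(rng.normal(5.4, 1.2), 1.0, 7.9)))
            else:
                latencies.append(np.nan)
        amps = rng.uniform(*amp_range_z, n_stimuli)
        truth = cls(
            paradigm="looming",
            duration=duration,
            event_schedule=schedule,
            event_amplitudes=amps,
            response_labels=labels,
            response_latencies=latencies,
            rng_seed=rng_seed,
            **overrides,
        )
        truth.validate()
        return truth


@dataclass
class SyntheticSession:
    recording: RawRecording
    events: "object"          # pandas.DataFrame event table
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def geci_kernel(rise_s: float, decay_s: float, fs: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials impulse response."""
    support = rise_s + 5 * decay_s
    t = np.arange(0.0, support, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _bleach_curve(t: np.ndarray, params) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, tau in params:
        out += amp * np.exp(-t / tau)
    return out


def _motion_waveform(t: np.ndarray, motion) -> np.ndarray:
    """Raised-cosine bumps shared verbatim by signal and isosbestic channels."""
    out = np.zeros_like(t)
    for onset, dur, amp in motion:
        mask = (t >= onset) & (t < onset + dur)
        out[mask] += amp * 0.5 * (1 - np.cos(2 * np.pi * (t[mask] - onset) / dur))
    return out


def _wander(t: np.ndarray, truth: SimulationTruth, rng) -> np.ndarray:
    """Slow basal fluctuation: sinusoids with periods tied to session length
    (full cycles, so the pre-detrend variance is exact) and seeded phases."""
    out = np.zeros_like(t)
    for period in truth.wander_periods:
        phase = rng.uniform(0, 2 * np.pi)
        out += truth.wander_sd * np.sin(2 * np.pi * t / period + phase)
    return out


def _replica_process(sig: np.ndarray, iso: np.ndarray, t: np.ndarray,
                     order: int, cutoff: float, fs: float) -> np.ndarray:
    """Minimal stand-in for the analysis signal path, used only to express
    ground truth in measurement units (deliberately written against
    numpy/scipy primitives, independent of the preprocess module)."""
    x = np.linspace(-1.0, 1.0, t.size)
    rs = sig - npoly.polyval(x, npoly.polyfit(x, sig, order))
    ri = iso - npoly.polyval(x, npoly.polyfit(x, iso, order))
    b, a = sps.butter(2, cutoff / (fs / 2))
    irlen = int(min(t.size - 1, round(10 * fs / cutoff)))
    return sps.filtfilt(b, a, rs - ri, method="gust", irlen=irlen)


def _noise_sd_factor(fs: float, cutoff: float) -> float:
    """SD gain of white noise through the zero-phase Butterworth (|H|^2 filter)."""
    b, a = sps.butter(2, cutoff / (fs / 2))
    w, h = sps.freqz(b, a, worN=8192)
    return float(np.sqrt(np.trapezoid(np.abs(h) ** 4, w) / np.pi))


def _filtered_kernel(kernel: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    b, a = sps.butter(2, cutoff / (fs / 2))
    pad = np.zeros(int(10 * fs))
    return sps.filtfilt(b, a, np.concatenate([pad, kernel, pad]))


def _spontaneous_onsets(truth: SimulationTruth, rng) -> np.ndarray:
    """Poisson onsets restricted to gaps that no analysis window touches."""
    window = WINDOW_BY_PARADIGM[truth.paradigm]
    support = truth.kernel_support_s()
    smear = 2.0  # acausal reach of the zero-phase filter
    fs = truth.sampling_rate
    tgrid = np.arange(0.0, truth.duration, 1.0 / fs)
    allowed = np.ones(tgrid.size, dtype=bool)
    for onset, _, _ in truth.event_schedule:
        lo = onset + window[0] - support - smear
        hi = onset + window[1] + smear
        allowed &= ~((tgrid >= lo) & (tgrid <= hi))
    allowed &= tgrid < truth.duration - support
    n_allowed = int(allowed.sum())
    if n_allowed == 0:
        return np.array([])
    n_events = min(rng.poisson(truth.spontaneous_rate * n_allowed / fs), n_allowed)
    if n_events == 0:
        return np.array([])
    idx = rng.choice(np.nonzero(allowed)[0], size=n_events, replace=False)
    return np.sort(tgrid[idx])


def _add_kernels(trace: np.ndarray, onsets, amps, kernel: np.ndarray, fs: float):
    for onset, amp in zip(onsets, np.broadcast_to(amps, (len(onsets),))):
        i0 = int(round(onset * fs))
        i1 = min(i0 + kernel.size, trace.size)
        if i0 < trace.size:
            trace[i0:i1] += amp * kernel[: i1 - i0]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _generate(truth: SimulationTruth) -> SyntheticSession:
    truth.validate()
    fs = truth.sampling_rate
    order = truth.analysis_poly_order
    cutoff = truth.analysis_cutoff_hz
    t = np.arange(0.0, truth.duration, 1.0 / fs)
    rng = np.random.default_rng([truth.rng_seed, 1])

    motion = _motion_waveform(t, truth.motion)
    sensors = {NEURON_SENSOR: ("sig_slow", "iso_slow"),
               ASTRO_SENSOR: ("sig_fast", "iso_fast")}

    # clean (noise-free, transient-free) per-channel scaffolds
    scaffold = {}
    for ch, offset in truth.channel_offsets.items():
        scaffold[ch] = offset + _bleach_curve(t, truth.bleach_params[ch]) + motion
    wander = {}
    for sensor, (sig_col, _) in sensors.items():
        wander[sensor] = _wander(t, truth, rng)
        scaffold[sig_col] = scaffold[sig_col] + wander[sensor]

    # spontaneous basal transients (independent per sensor, outside windows)
    kernels = {
        s: geci_kernel(*truth.transient_kinetics[s], fs) for s in sensors
    }
    spont = {}
    for sensor, (sig_col, _) in sensors.items():
        onsets = _spontaneous_onsets(truth, rng)
        amps = truth.spontaneous_amp * rng.lognormal(0.0, 0.3, onsets.size)
        spont[sensor] = (onsets, amps)
        _add_kernels(scaffold[sig_col], onsets, amps, kernels[sensor], fs)

    # z-unit calibration: predicted basal SD of the processed clean trace
    # plus the analytic filtered-noise variance (evoked transients contribute
    # < ~2% of variance at default amplitudes and are ignored; see docs)
    nb = _noise_sd_factor(fs, cutoff)
    zeta = {}
    for sensor, (sig_col, iso_col) in sensors.items():
        clean = _replica_process(scaffold[sig_col], scaffold[iso_col], t,
                                 order, cutoff, fs)
        var_noise = 2 * (truth.noise_sd * nb) ** 2
        zeta[sensor] = float(np.sqrt(np.var(clean) + var_noise))

    fk = {s: _filtered_kernel(kernels[s], fs, cutoff) for s in sensors}
    att = {s: float(fk[s].max()) for s in sensors}
    # astro kernel value at the (filtered) neuron peak lag: the peak-anchored
    # pairing samples the astro trace there, so calibrate against it
    g_astro = float(fk[ASTRO_SENSOR][int(np.argmax(fk[NEURON_SENSOR]))])

    # evoked transients
    n_ev = len(truth.event_schedule)
    if truth.event_amplitudes is None:
        neuron_amps_z = rng.uniform(0.15, 0.5, n_ev)
    else:
        neuron_amps_z = np.asarray(truth.event_amplitudes, dtype=float)
        if neuron_amps_z.size != n_ev:
            raise ValueError(
                f"{neuron_amps_z.size} amplitudes for {n_ev} scheduled events"
            )
    astro_amps_z = (
        truth.coupling_slope * neuron_amps_z
        + truth.coupling_intercept
        + rng.normal(0.0, truth.coupling_noise_sd, n_ev)
    )
    if truth.paradigm == "looming":
        gains = np.array([truth.response_gain[lab] for lab in truth.response_labels])
        neuron_amps_z = neuron_amps_z * gains
        astro_amps_z = astro_amps_z * gains
        transient_onsets = [
            ev[0] + truth.loom_transient_onset_s for ev in truth.event_schedule
        ]
    else:
        transient_onsets = [ev[0] for ev in truth.event_schedule]

    channels = {ch: arr.copy() for ch, arr in scaffold.items()}
    _add_kernels(
        channels[sensors[NEURON_SENSOR][0]], transient_onsets,
        neuron_amps_z * zeta[NEURON_SENSOR] / att[NEURON_SENSOR],
        kernels[NEURON_SENSOR], fs,
    )
    _add_kernels(
        channels[sensors[ASTRO_SENSOR][0]], transient_onsets,
        astro_amps_z * zeta[ASTRO_SENSOR] / g_astro,
        kernels[ASTRO_SENSOR], fs,
    )

    # QC-test glitches: boxcar bumps in a sensor's signal channel, amplitude in z
    for gtime, gdur, gamp_z, sensor in truth.baseline_glitches:
        sig_col = sensors[sensor][0]
        mask = (t >= gtime) & (t < gtime + gdur)
        channels[sig_col][mask] += gamp_z * zeta[sensor]

    for ch in channels:
        channels[ch] = channels[ch] + rng.normal(0.0, truth.noise_sd, t.size)

    recording = RawRecording(
        time=t,
        channels=channels,
        sensors=sensors,
        subject_id=truth.subject_id,
        sex=truth.sex,
    )
    return SyntheticSession(recording=recording, events=None, truth=truth)


def generate_social_session(truth: SimulationTruth) -> SyntheticSession:
    """Synthesize one home-cage social session (recording + sniff event table)."""
    if truth.paradigm != "social":
        raise ValueError("truth.paradigm must be 'social'")
    session = _generate(truth)
    rows = [
        {
            "subject_id": truth.subject_id,
            "event_type": "sniff",
            "start_s": onset,
            "stop_s": offset,
            "sex": truth.sex,
            "familiarity": truth.familiarity,
        }
        for onset, offset, _ in truth.event_schedule
    ]
    session.events = make_event_table(rows)
    return session


def generate_looming_session(truth: SimulationTruth) -> SyntheticSession:
    """Synthesize one looming-shadow session (recording + stimulus/response rows)."""
    if truth.paradigm != "looming":
        raise ValueError("truth.paradigm must be 'looming'")
    n = len(truth.event_schedule)
    if not 6 <= n <= 8:
        raise ValueError(f"stimulus count must be 6-8, got {n}")
    onsets = np.array([ev[0] for ev in truth.event_schedule])
    if onsets.size >= 2 and np.min(np.diff(onsets)) < MIN_LOOM_SPACING_S:
        raise ValueError(
            f"looming stimuli must be >= {MIN_LOOM_SPACING_S:.0f} s apart "
            f"(min gap {np.min(np.diff(onsets)):.1f} s)"
        )
    session = _generate(truth)
    rows = []
    for k, (onset, offset, _) in enumerate(truth.event_schedule):
        lab = truth.response_labels[k]
        lat = truth.response_latencies[k]
        rows.append(
            {
                "subject_id": truth.subject_id,
                "event_type": "loom_stimulus",
                "start_s": onset,
                "stop_s": offset,
                "sex": truth.sex,
                "response_category": lab,
                "latency_s": lat,
            }
        )
        if lab == "run":
            rows.append(
                {
                    "subject_id": truth.subject_id,
                    "event_type": "run",
                    "start_s": onset + lat,
                    "stop_s": onset + lat + 1.0,
                    "sex": truth.sex,
                    "response_category": lab,
                }
            )
        elif lab == "freeze":
            rng = np.random.default_rng([truth.rng_seed, 303, k])
            dur = float(np.clip(rng.normal(17.0, 4.0), 2.0, 40.0))
            rows.append(
                {
                    "subject_id": truth.subject_id,
                    "event_type": "freeze",
                    "start_s": onset + lat,
                    "stop_s": onset + lat + dur,
                    "sex": truth.sex,
                    "response_category": lab,
                }
            )
    session.events = make_event_table(rows)
    return session
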