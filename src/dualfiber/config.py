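"""Analysis configuration: one flat key-value object, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the signal path and QC.

    Defaults reproduce the published analysis settings; anything the original
    description leaves open (polynomial order, isosbestic rescaling, basal
    window) is exposed here with the documented default.
    """

    # preprocessing
    poly_order: int = 2                 # baseline-correction polynomial order
    filter_cutoff_hz: float = 0.3       # zero-phase low-pass cutoff
    isosbestic_rescale: bool = False    # OLS-rescale isosbestic before subtracting
    basal_window: tuple[float, float] | None = None  # None = whole session
    decimate_to_hz: float = 100.0       # anti-aliased decimation target for >100 Hz input
    max_nan_gap_s: float = 0.0          # NaN runs longer than this reject the recording

    # trial QC (social values; looming uses AlignmentSpec.looming overrides)
    min_bout_s: float = 1.0
    min_events_per_subject: int = 4     # subjects with <= 3 qualifying events excluded
    baseline_irregularity_z: float = 0.2
    max_trials_per_subject: int = 5
    irregularity_mode: str = "any_sample"  # or "window_mean"

    # peak detection
    ignore_fraction_social: float = 0.05
    ignore_fraction_looming: float = 0.10

    # statistics
    auto_normality: bool = True         # Shapiro-Wilk gate for t vs rank tests
    fdr_alpha: float = 0.05
    rout_q: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "basal_window" in raw and raw["basal_window"] is not None:
            raw["basal_window"] = tuple(raw["basal_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        if data["basal_window"] is not None:
            data["basal_window"] = list(data["basal_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
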