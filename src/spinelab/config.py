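"""Analysis configuration: acquisition constants, windows, thresholds.

Defaults reproduce the standard experiment: 2.6-ns fixed donor lifetime,
7.8-Hz frame rate with 0.128-s frame interval, 16-frame / 2.048-s sweeps
with 7 baseline sweeps, pulses 2-18 averaged, 0.45 baseline-binding QC
threshold, and the 10-s release-time bins over the 60-s stimulation span.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # acquisition
    tau_d_ns: float = 2.6
    tau_ad_ns: float = 1.3
    period_ns: float = 25.0
    n_bins: int = 256
    frame_rate_hz: float = 7.8
    frame_interval_s: float = 0.128
    # sweeps
    frames_per_sweep: int = 16
    n_baseline_sweeps: int = 7
    pulse_range: tuple[int, int] = (2, 18)
    # time-course analysis
    baseline_n: int = 7
    phase_windows_min: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("transient", 1.0, 3.0),
            ("sustained_9_11", 9.0, 11.0),
            ("sustained_12_15", 12.0, 15.0),
        ]
    )
    # thresholds / QC
    qc_baseline_threshold: float = 0.45
    min_photons_image: int = 10_000
    min_photons_pixel: int = 10
    min_photons_roi: int = 100
    # events
    event_bin_width_s: float = 10.0
    stim_window_s: tuple[float, float] = (4.0, 64.0)
    basal_window_s: tuple[float, float] = (0.0, 60.0)
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulse_range"] = list(self.pulse_range)
        d["stim_window_s"] = list(self.stim_window_s)
        d["basal_window_s"] = list(self.basal_window_s)
        d["phase_windows_min"] = [list(w) for w in self.phase_windows_min]
        return d

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pulse_range", "stim_window_s", "basal_window_s"):
            if key in data:
                data[key] = tuple(data[key])
        if "phase_windows_min" in data:
            data["phase_windows_min"] = [tuple(w) for w in data["phase_windows_min"]]
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
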