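"""Run configuration: one JSON document per run.

Every tunable of the pipelines lives here with a default equal to the study
condition it models where one exists: the 0.01-0.1 Hz BOLD band, the
-5.5 s.d. spike threshold, the >=5-spike / <50 ms burst rule, b = 800 s mm^-2
with 60 directions, 0.1 um g-ratio bins over [0.3, 1.5] um, and alpha 0.05.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    # rsfMRI
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    sampling_interval_s: float = 2.0
    n_timepoints: int = 150
    # DTI
    b_value: float = 800.0
    n_directions: int = 60
    # MEA
    spike_threshold_sd: float = 5.5
    spike_dead_time_s: float = 0.001
    highpass_hz: float = 100.0
    mea_sampling_hz: float = 10_000.0
    burst_min_spikes: int = 5
    burst_max_isi_s: float = 0.050
    active_min_rate_hz: float = 0.01
    # EM
    pixel_size_nm: float = 7.0
    gratio_bin_edges_um: list[float] = field(
        default_factory=lambda: [round(0.3 + 0.1 * i, 10) for i in range(13)])
    # statistics
    alpha: float = 0.05
    # paths
    input_path: str | None = None
    output_path: str | None = None

    def __post_init__(self):
        if self.seed < 0:
            raise ValidationError("seed must be >= 0")
        nyquist = 0.5 / self.sampling_interval_s
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise ValidationError(
                f"need 0 < low ({self.band_low_hz}) < high ({self.band_high_hz})"
                f" < Nyquist ({nyquist})")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.spike_threshold_sd <= 0:
            raise ValidationError("spike threshold multiple must be positive")
        edges = self.gratio_bin_edges_um
        if any(b >= a for a, b in zip(edges[1:], edges[:-1])):
            raise ValidationError("bin edges must be strictly increasing")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
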