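"""Pipeline configuration with the analysis defaults.

Every default mirrors the analysis convention the pipeline implements:
6th-order causal Butterworth high-pass at 1 Hz; 1-s Hamming spectrogram
windows with no overlap; 3-MAD session-level artifact threshold; 4-s
Welch windows with 50% overlap and next-power-of-two FFT length; 10-14 Hz
tremor-band search with a 17-21 Hz reference band; 900-s baseline cutoff;
FDR 1e-4; 15-minute drift-fit cutoff. The full configuration is embedded
in every emitted report for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # high-pass filter
    filter_order: int = 6
    highpass_cutoff_hz: float = 1.0
    zero_phase: bool = False
    apply_highpass: bool = True
    # segmentation
    max_segment_s: float = 120.0
    min_remainder_s: float = 4.0
    # spectrogram
    spectrogram_window_s: float = 1.0
    # artifact rejection
    artifact_n_mad: float = 3.0
    # Welch PSD
    welch_window_s: float = 4.0
    welch_overlap: float = 0.5
    # bands
    tremor_band: tuple[float, float] | None = None  # None = auto-select
    band_search_range: tuple[float, float] = (8.0, 16.0)
    band_half_width: float = 2.0
    reference_band: tuple[float, float] = (17.0, 21.0)
    peak_search_band: tuple[float, float] = (10.0, 14.0)
    # statistics
    baseline_cutoff_s: float = 900.0
    fdr: float = 1e-4
    drift_cutoff_min: float = 15.0
    ci_level: float = 0.95
    n_boot: int = 1000
    bootstrap_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
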