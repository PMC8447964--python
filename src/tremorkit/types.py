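"""Core data containers shared across the pipeline.

All times are in seconds relative to the injection event (negative means
pre-injection); reporting layers may convert to minutes. Acceleration is in
arbitrary units: every statistic downstream (motion power ratio, artifact
mask, signed-rank tests) is invariant to a global rescaling, so no
g-calibration is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

__all__ = [
    "TriaxSegment",
    "Session",
    "SummedSpectrogram",
    "ArtifactMask",
    "PSDEstimate",
    "BandDefinition",
    "MPRSeries",
    "BaselineStats",
    "SegmentStat",
    "OnsetResult",
    "DriftFit",
    "TaskSession",
    "DoseResponse",
]


@dataclass
class TriaxSegment:
    """One episodic recording: three acceleration channels at a uniform rate.

    Parameters
    ----------
    channels : ndarray, shape (3, n)
        Acceleration along the three orthogonal accelerometer axes.
    sampling_rate : float
        Samples per second (subject-specific, e.g. 617, 500 or 1017.3).
    start_time : float
        Segment start in seconds relative to injection (negative =
        pre-injection).
    """

    channels: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    subject_id: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 3:
            raise InputError(
                f"expected 3 acceleration channels, got array of shape "
                f"{self.channels.shape}"
            )
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def midpoint_time(self) -> float:
        return self.start_time + 0.5 * self.duration

    def times(self) -> np.ndarray:
        """Per-sample times in seconds relative to injection."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class Session:
    """Subject/dose metadata plus an ordered collection of segments.

    Segments are kept sorted by start time and must not overlap. The
    injection event defines time zero for every segment.
    """

    subject_id: str
    dose_mg_per_kg: float
    segments: list[TriaxSegment] = field(default_factory=list)
    truth: object | None = None  # ground truth attached by the simulator

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start_time)
        for a, b in zip(self.segments, self.segments[1:]):
            if a.start_time + a.duration > b.start_time + 1e-9:
                raise InputError(
                    f"segments {a.segment_id!r} and {b.segment_id!r} overlap"
                )


@dataclass
class SummedSpectrogram:
    """Per-window power over frequency, summed across the three axes.

    Windows are non-overlapping Hamming-tapered stretches of nominally one
    second; ``window_times`` are window midpoints relative to injection.
    """

    window_times: np.ndarray
    freq_bins: np.ndarray
    power: np.ndarray  # (n_windows, n_bins), >= 0
    source_segment_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]

    def window_power(self) -> np.ndarray:
        """Summed spectral power of each window (sum over frequency)."""
        return self.power.sum(axis=1)


@dataclass
class ArtifactMask:
    """Keep/drop decision per 1-s window, pooled over a whole session.

    The median and MAD are computed over *all* windows of the session, not
    per segment; ``keep`` is stored per segment for alignment.
    """

    keep: dict[str, np.ndarray]  # segment_id -> boolean per window
    session_median_power: float
    session_mad_power: float

    @property
    def n_windows(self) -> int:
        return sum(len(k) for k in self.keep.values())

    @property
    def n_kept(self) -> int:
        return sum(int(k.sum()) for k in self.keep.values())


@dataclass
class PSDEstimate:
    """Welch power spectral density of one cleaned segment, axes summed."""

    freqs: np.ndarray
    power_density: np.ndarray
    nfft: int
    segment_id: str = ""
    segment_midpoint_time: float = 0.0

    @property
    def resolution(self) -> float:
        """Frequency bin spacing in Hz (= sampling_rate / nfft)."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandDefinition:
    """Tremor and reference frequency bands, half-open ``[lo, hi)`` in Hz."""

    tremor_band: tuple[float, float] = (10.0, 14.0)
    reference_band: tuple[float, float] = (17.0, 21.0)
    secondary_band: tuple[float, float] | None = None
    fallback: bool = False  # True when auto-selection fell back to default

    def __post_init__(self) -> None:
        for lo, hi in filter(None, (self.tremor_band, self.reference_band,
                                    self.secondary_band)):
            if not lo < hi:
                raise InputError(f"band ({lo}, {hi}) is empty")
        t, r = self.tremor_band, self.reference_band
        if max(t[0], r[0]) < min(t[1], r[1]):
            raise InputError("tremor and reference bands overlap")


@dataclass
class MPRSeries:
    """Motion power ratio per kept 1-s window.

    ``mpr`` is tremor-band power divided by reference-band power;
    ``normalized_mpr`` is ``mpr`` divided by the baseline median (filled
    after the baseline is known).
    """

    window_times: np.ndarray
    mpr: np.ndarray
    bands: BandDefinition
    segment_ids: np.ndarray  # segment id per window
    normalized_mpr: np.ndarray | None = None


@dataclass
class BaselineStats:
    """Median MPR over all baseline windows (time <= cutoff)."""

    baseline_median_mpr: float
    n_baseline_windows: int
    baseline_cutoff: float = 900.0


@dataclass
class SegmentStat:
    """Per-segment summary of normalized MPR versus baseline."""

    segment_id: str
    midpoint_time: float  # seconds
    n_windows: int
    median_normalized_mpr: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: str  # "above" | "below" | "none"
    bh_reject: bool = False


@dataclass
class OnsetResult:
    """Earliest post-baseline segment significantly above baseline."""

    onset_time: float | None  # minutes post-injection, None if no onset
    onset_segment_id: str | None = None

    @property
    def detected(self) -> bool:
        return self.onset_time is not None


@dataclass
class DriftFit:
    """First-order linear fit of peak tremor frequency over time."""

    slope: float  # Hz / minute
    intercept: float  # Hz
    slope_ci_low: float
    slope_ci_high: float
    n_points: int
    excluded_points: list[int] = field(default_factory=list)


@dataclass
class TaskSession:
    """One self-paced cued reaching session (dose 0 = drug-naive)."""

    dose_mg_per_kg: float
    session_minutes: float
    attempted_reaches: int
    premature_reaches: int

    def __post_init__(self) -> None:
        if self.session_minutes <= 0:
            raise InputError("session_minutes must be positive")
        if not 0 <= self.premature_reaches <= self.attempted_reaches:
            raise InputError(
                "premature_reaches must be between 0 and attempted_reaches"
            )

    @property
    def premature_fraction(self) -> float | None:
        """Within-session premature fraction; None when no reaches occurred."""
        if self.attempted_reaches == 0:
            return None
        return self.premature_reaches / self.attempted_reaches


@dataclass
class DoseResponse:
    """Pearson dose-response summary for one task metric."""

    metric: str
    doses: np.ndarray
    means: np.ndarray
    pearson_r: float
    p_value: float

    @property
    def n_points(self) -> int:
        return len(self.doses)
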