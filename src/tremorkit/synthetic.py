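"""Seeded generator of triaxial accelerometry sessions and reach-task logs.

The generator emulates the statistical structure the analysis assumes in a
wrist-accelerometry recording of a seated primate after a tremorgenic
harmaline dose:

* background motion — broadband white noise plus a low-pass (< 5 Hz)
  filtered component mimicking slow postural drift;
* a 10-14 Hz tremor oscillation appearing at a configurable onset time
  (typically 20-30 minutes post-injection), synthesized as a chirp whose
  instantaneous frequency declines linearly (the instantaneous phase is
  the integral of the drifting frequency, so there are no phase
  discontinuities);
* amplitude intermittency — a seeded Bernoulli gate on 1-s epochs aligned
  with the analysis windows, smoothed by a 0.1-s raised-cosine ramp, plus
  a slow stochastic amplitude envelope;
* brief high-amplitude broadband transients ("jerk" artifacts) at a
  configurable rate. Each artifact is placed entirely within a single
  1-s analysis window so ground-truth window labels are unambiguous.

Tremor is projected onto the three axes with fixed unit-vector weights;
the analysis sums the three axis spectrograms, so the projection only
needs to be configurable, not realistic. Amplitudes are expressed in
units of the broadband noise standard deviation (the analysis is
scale-invariant, so no physical calibration is modelled).

Identical profiles, plan and seed produce bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError
from .types import Session, TaskSession, TriaxSegment

__all__ = [
    "TremorProfile",
    "NoiseProfile",
    "SessionPlan",
    "TaskPlan",
    "GroundTruth",
    "simulate_session",
    "simulate_task_sessions",
]


@dataclass
class TremorProfile:
    """Parameters of the simulated tremor oscillation.

    Defaults reflect a robust harmaline response: a ~12 Hz oscillation
    appearing 25 minutes post-injection, drifting down slowly and active
    in most 1-s epochs. The amplitude default (1.5x the broadband noise
    SD) keeps the tremor narrowband-dominant — overwhelming in the
    tremor-band power ratio — without dominating *total* window power,
    since on a wrist sensor the broadband postural/motion background
    carries most of the overall power.
    """

    onset_time: float = 1500.0  # s post-injection
    peak_freq_at_onset: float = 12.0  # Hz
    drift_slope: float = -0.015  # Hz / minute (<= 0 typical)
    amplitude: float = 1.5  # in units of broadband noise SD
    intermittency_duty: float = 0.8  # fraction of active 1-s epochs
    envelope_timescale: float = 30.0  # s, slow amplitude modulation
    envelope_depth: float = 0.3  # relative SD of the slow envelope
    axis_weights: tuple[float, float, float] = (0.7, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ConfigurationError("onset_time must be >= 0")
        if not 0 <= self.intermittency_duty <= 1:
            raise ConfigurationError("intermittency_duty must be in [0, 1]")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")

    def instantaneous_freq(self, t: np.ndarray) -> np.ndarray:
        """Programmed frequency (Hz) at times ``t`` (s post-injection)."""
        tau = np.maximum(np.asarray(t, dtype=float) - self.onset_time, 0.0)
        return self.peak_freq_at_onset + (self.drift_slope / 60.0) * tau


@dataclass
class NoiseProfile:
    """Background-motion and artifact parameters (acceleration units)."""

    broadband_sd: float = 1.0
    low_freq_motion_sd: float = 0.5  # postural drift, < 5 Hz
    artifact_rate: float = 1.0  # events / minute
    artifact_amplitude_factor: float = 10.0  # x broadband_sd
    artifact_duration: float = 0.2  # s, < 1 so it fits one window

    def __post_init__(self) -> None:
        for name in ("broadband_sd", "low_freq_motion_sd", "artifact_rate",
                     "artifact_amplitude_factor", "artifact_duration"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.artifact_duration >= 1.0:
            raise ConfigurationError(
                "artifact_duration must be < 1 s (one analysis window)")


@dataclass
class SessionPlan:
    """Recording schedule: which stretches of the session are sampled.

    ``segment_schedule`` is a sorted list of non-overlapping
    ``(start_time_s, duration_s)`` pairs relative to injection; at least
    one segment must lie entirely within the baseline period
    (start + duration <= 900 s).
    """

    sampling_rate: float = 500.0
    segment_schedule: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not self.segment_schedule:
            raise ConfigurationError("segment_schedule is empty")
        sched = sorted(self.segment_schedule, key=lambda x: x[0])
        if sched != list(self.segment_schedule):
            raise ConfigurationError("segment_schedule must be time-sorted")
        for (s0, d0), (s1, _) in zip(sched, sched[1:]):
            if s0 + d0 > s1:
                raise ConfigurationError("segments overlap in the schedule")
        if not any(s + d <= 900.0 for s, d in sched):
            raise ConfigurationError(
                "schedule needs at least one segment entirely within the "
                "baseline period (start + duration <= 900 s)")

    @classmethod
    def regular(
        cls,
        sampling_rate: float = 500.0,
        pre_injection_segments: int = 2,
        baseline_segment_s: float = 120.0,
        early_post_segment: bool = True,
        post_start: float = 900.0,
        post_end: float = 2700.0,
        segment_len: float = 60.0,
        seed: int = 0,
    ) -> "SessionPlan":
        """Episodic schedule: pre-injection baseline recordings, one early
        post-injection recording inside the baseline window, then
        contiguous ``segment_len``-s segments from ``post_start`` to
        ``post_end``."""
        sched: list[tuple[float, float]] = [
            (-(i + 1) * (baseline_segment_s + 180.0), baseline_segment_s)
            for i in reversed(range(pre_injection_segments))
        ]
        if early_post_segment:
            sched.append((300.0, baseline_segment_s))
        t = post_start
        while t + segment_len <= post_end + 1e-9:
            sched.append((t, segment_len))
            t += segment_len
        return cls(sampling_rate=sampling_rate, segment_schedule=sched,
                   seed=seed)

    @property
    def end_time(self) -> float:
        return max(s + d for s, d in self.segment_schedule)


@dataclass
class TaskPlan:
    """Reach-task study plan: dose list and linear dose effects."""

    doses: list[float] = field(default_factory=lambda: [0.0, 2.0, 4.0, 6.0, 8.0])
    baseline_reaches: float = 120.0  # expected attempts at dose 0
    engagement_slope: float = -12.0  # change in expected attempts per mg/kg
    baseline_premature_frac: float = 0.05
    premature_slope: float = 0.03  # change in premature fraction per mg/kg
    session_minutes: float = 30.0
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.doses:
            raise ConfigurationError("dose list is empty")
        if len(set(self.doses)) < 3:
            raise ConfigurationError("need at least 3 distinct doses")


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    onset_time: float | None  # s post-injection, None for noise-only
    tremor: TremorProfile | None
    noise: NoiseProfile
    artifact_windows: dict[str, list[int]]  # segment_id -> window indices


def _lowpass_noise(rng: np.random.Generator, shape, fs: float,
                   cutoff_hz: float, target_sd: float) -> np.ndarray:
    """Low-pass filtered white noise rescaled to the target SD per row."""
    x = rng.standard_normal(shape)
    if cutoff_hz < fs / 2:
        sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs,
                            output="sos")
        x = signal.sosfilt(sos, x, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * target_sd


def _smooth_gate(gate_epochs: np.ndarray, nper: int, n: int, fs: float,
                 ramp_s: float = 0.1) -> np.ndarray:
    """Per-sample gate from per-epoch draws, raised-cosine 0.1-s ramps."""
    g = np.zeros(n)
    full = np.repeat(gate_epochs.astype(float), nper)
    g[: len(full)] = full[:n]
    m = int(round(ramp_s * fs))
    if m >= 2:
        kernel = np.hanning(m)
        kernel /= kernel.sum()
        g = np.convolve(g, kernel, mode="same")
    return g


def simulate_session(
    tremor: TremorProfile | None,
    noise: NoiseProfile,
    plan: SessionPlan,
    subject_id: str = "sim",
    dose_mg_per_kg: float = 10.0,
) -> Session:
    """Generate one seeded accelerometry session.

    ``tremor=None`` (or zero amplitude) yields a noise-only session. The
    returned :class:`~tremorkit.types.Session` carries a
    :class:`GroundTruth` in its ``truth`` attribute.
    """
    if tremor is not None and tremor.amplitude > 0:
        f_end = tremor.instantaneous_freq(plan.end_time)
        if f_end <= 0:
            raise ConfigurationError(
                f"drift drives the tremor frequency to {f_end:.2f} Hz "
                "within the session; must stay positive")
    rng = np.random.default_rng(plan.seed)
    fs = plan.sampling_rate
    weights = None
    if tremor is not None:
        w = np.asarray(tremor.axis_weights, dtype=float)
        weights = w / np.linalg.norm(w)

    segments: list[TriaxSegment] = []
    artifact_windows: dict[str, list[int]] = {}
    for k, (start, dur) in enumerate(plan.segment_schedule):
        n = int(round(dur * fs))
        t = start + np.arange(n) / fs
        sid = f"seg{k:03d}"
        data = rng.normal(0.0, noise.broadband_sd, size=(3, n))
        if noise.low_freq_motion_sd > 0:
            data += _lowpass_noise(rng, (3, n), fs, 5.0,
                                   noise.low_freq_motion_sd)

        if tremor is not None and tremor.amplitude > 0:
            nper = int(round(fs))
            nwin = max(n // nper, 1)
            gate_epochs = rng.random(nwin) < tremor.intermittency_duty
            gate = _smooth_gate(gate_epochs, nper, n, fs)
            env = 1.0 + tremor.envelope_depth * _lowpass_noise(
                rng, (1, n), fs, 1.0 / max(tremor.envelope_timescale, 1e-6),
                1.0)[0]
            env = np.clip(env, 0.0, None)
            tau = np.maximum(t - tremor.onset_time, 0.0)
            slope_s = tremor.drift_slope / 60.0
            phase = 2 * np.pi * (tremor.peak_freq_at_onset * tau
                                 + 0.5 * slope_s * tau**2)
            active = (t >= tremor.onset_time).astype(float)
            x = tremor.amplitude * env * gate * active * np.sin(phase)
            data += weights[:, None] * x[None, :]

        art: list[int] = []
        if noise.artifact_rate > 0 and noise.artifact_duration > 0:
            nper = int(round(fs))
            nwin = n // nper
            n_art = rng.poisson(noise.artifact_rate * dur / 60.0)
            m = int(round(noise.artifact_duration * fs))
            for _ in range(n_art):
                if nwin == 0 or m >= nper:
                    break
                w_idx = int(rng.integers(0, nwin))
                off = int(rng.integers(0, nper - m + 1))
                s0 = w_idx * nper + off
                burst = rng.normal(
                    0.0,
                    noise.artifact_amplitude_factor * noise.broadband_sd,
                    size=(3, m))
                data[:, s0:s0 + m] += burst
                art.append(w_idx)
        artifact_windows[sid] = sorted(set(art))

        segments.append(TriaxSegment(
            channels=data, sampling_rate=fs, start_time=start,
            subject_id=subject_id, segment_id=sid))

    truth = GroundTruth(
        onset_time=(tremor.onset_time
                    if tremor is not None and tremor.amplitude > 0 else None),
        tremor=tremor,
        noise=noise,
        artifact_windows=artifact_windows,
    )
    return Session(subject_id=subject_id, dose_mg_per_kg=dose_mg_per_kg,
                   segments=segments, truth=truth)


def simulate_task_sessions(plan: TaskPlan) -> list[TaskSession]:
    """Generate one reach-task session per listed dose.

    Attempted-reach counts are Poisson with mean linear in dose; premature
    counts are binomial given the (clipped) linear premature fraction.
    ``deterministic=True`` replaces the draws with rounded expectations.
    """
    rng = np.random.default_rng(plan.seed)
    out: list[TaskSession] = []
    for dose in plan.doses:
        mean_reaches = max(0.0,
                           plan.baseline_reaches
                           + plan.engagement_slope * dose)
        frac = float(np.clip(
            plan.baseline_premature_frac + plan.premature_slope * dose,
            0.0, 1.0))
        if plan.deterministic:
            attempted = int(round(mean_reaches))
            premature = int(round(frac * attempted))
        else:
            attempted = int(rng.poisson(mean_reaches))
            premature = int(rng.binomial(attempted, frac))
        out.append(TaskSession(
            dose_mg_per_kg=float(dose),
            session_minutes=plan.session_minutes,
            attempted_reaches=attempted,
            premature_reaches=premature,
        ))
    return out
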