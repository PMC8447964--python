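"""Raw-segment conditioning: linear detrend, 1 Hz high-pass, segmentation.

The processing order is detrend first, then high-pass filter, applied to
each channel independently. Filtering is single-pass (causal) by default;
a zero-phase forward-backward variant is available but doubles the
effective filter order, so it is off unless requested. No padding is used:
the filter's initial-condition transient (well under 3 s at a 1 Hz cutoff)
is accepted since analysis segments are a minute or longer.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, InputError
from .types import Session, TriaxSegment

__all__ = [
    "detrend_linear",
    "highpass",
    "preprocess_segment",
    "preprocess_session",
    "segment_stream",
]


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Subtract the ordinary-least-squares straight line from ``series``.

    The residual has zero mean and zero OLS slope. Works on a 1-D series or
    row-wise on a (channels, n) array.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise InputError("detrend_linear requires at least 2 samples")
    return signal.detrend(series, axis=-1, type="linear")


def highpass(
    series: np.ndarray,
    sampling_rate: float,
    cutoff_hz: float = 1.0,
    order: int = 6,
    zero_phase: bool = False,
) -> np.ndarray:
    """Butterworth high-pass filter, applied along the last axis.

    Default is the 6th-order causal (single-pass) filter at a 1 Hz cutoff.
    ``zero_phase=True`` runs the filter forward and backward instead.
    """
    if cutoff_hz >= sampling_rate / 2:
        raise ConfigurationError(
            f"high-pass cutoff {cutoff_hz} Hz is not below the Nyquist "
            f"frequency {sampling_rate / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass",
                        fs=sampling_rate, output="sos")
    series = np.asarray(series, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, series, axis=-1)
    return signal.sosfilt(sos, series, axis=-1)


def preprocess_segment(
    segment: TriaxSegment,
    cutoff_hz: float = 1.0,
    order: int = 6,
    zero_phase: bool = False,
    apply_highpass: bool = True,
) -> TriaxSegment:
    """Detrend then high-pass each channel of a segment."""
    data = detrend_linear(segment.channels)
    if apply_highpass:
        data = highpass(data, segment.sampling_rate, cutoff_hz=cutoff_hz,
                        order=order, zero_phase=zero_phase)
    return TriaxSegment(
        channels=data,
        sampling_rate=segment.sampling_rate,
        start_time=segment.start_time,
        subject_id=segment.subject_id,
        segment_id=segment.segment_id,
    )


def preprocess_session(session: Session, **kwargs) -> Session:
    """Apply :func:`preprocess_segment` to every segment of a session."""
    return Session(
        subject_id=session.subject_id,
        dose_mg_per_kg=session.dose_mg_per_kg,
        segments=[preprocess_segment(s, **kwargs) for s in session.segments],
        truth=session.truth,
    )


def segment_stream(
    segment: TriaxSegment,
    max_len_s: float = 120.0,
    min_remainder_s: float = 4.0,
) -> list[TriaxSegment]:
    """Split a continuous stream into consecutive chunks of <= ``max_len_s``.

    A trailing remainder shorter than ``min_remainder_s`` (one Welch window)
    is dropped. Chunk start times are carried relative to injection.
    """
    if segment.n_samples == 0:
        raise InputError("cannot segment an empty stream")
    fs = segment.sampling_rate
    chunk_n = int(round(max_len_s * fs))
    min_n = int(round(min_remainder_s * fs))
    out: list[TriaxSegment] = []
    for k, offset in enumerate(range(0, segment.n_samples, chunk_n)):
        chunk = segment.channels[:, offset:offset + chunk_n]
        if chunk.shape[1] < chunk_n and chunk.shape[1] < min_n:
            break  # trailing remainder below one Welch window: drop
        sid = segment.segment_id
        out.append(TriaxSegment(
            channels=chunk,
            sampling_rate=fs,
            start_time=segment.start_time + offset / fs,
            subject_id=segment.subject_id,
            segment_id=f"{sid}.{k}" if segment.n_samples > chunk_n else sid,
        ))
    return out
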