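"""Spectral analysis: summed spectrograms, artifact rejection, Welch PSDs,
peak tracking and the motion power ratio (MPR).

The spectrogram uses non-overlapping Hamming-tapered windows of nominally
one second (``round(sampling_rate)`` samples, so the bin spacing is
``sampling_rate / nperseg`` = ~1 Hz even at non-integer rates such as
1017.3 samples/s). Per-axis magnitude-squared short-time Fourier transforms
are summed bin-wise over the three axes, so the statistic is insensitive to
how the tremor projects onto the accelerometer axes.

Artifact rejection follows a robust session-level rule: any 1-s window
whose total spectral power deviates from the session median by more than
3 median absolute deviations (MAD, unscaled — no 1.4826 consistency
factor) is excluded. Because brief jerks leak power broadly across
frequency, they inflate total window power and are caught by this rule.

The MPR of a window is the summed power in a narrow tremor band (default
10-14 Hz) divided by the power in a fixed reference band (17-21 Hz) that
sits above the tremor range but within ordinary movement bandwidth. Band
intervals are half-open ``[lo, hi)`` on the frequency grid so adjacent
bands never double-count a shared endpoint. MPR is a ratio, hence
invariant to any global rescaling of the acceleration signal.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, InputError
from .types import (
    ArtifactMask,
    BandDefinition,
    MPRSeries,
    PSDEstimate,
    SummedSpectrogram,
    TriaxSegment,
)

__all__ = [
    "summed_spectrogram",
    "reject_artifacts",
    "concatenate_clean",
    "welch_window_and_nfft",
    "welch_psd",
    "peak_frequency",
    "band_slice",
    "motion_power_ratio",
    "mpr_series",
    "select_tremor_band",
]


def summed_spectrogram(
    segment: TriaxSegment, window_s: float = 1.0
) -> SummedSpectrogram:
    """Non-overlapping Hamming STFT power, summed over the three axes.

    The trailing partial window is dropped. Power is one-sided
    magnitude-squared without density scaling (downstream statistics are
    ratio- or rank-based, so the absolute scale is immaterial but fixed).
    """
    fs = segment.sampling_rate
    nperseg = int(round(fs * window_s))
    n_win = segment.n_samples // nperseg
    if n_win < 1:
        raise InputError(
            f"segment {segment.segment_id!r} shorter than one "
            f"{window_s}-s spectrogram window"
        )
    taper = np.hamming(nperseg)
    frames = segment.channels[:, : n_win * nperseg].reshape(3, n_win, nperseg)
    spec = np.fft.rfft(frames * taper, axis=-1)
    power = (spec.real**2 + spec.imag**2).sum(axis=0)  # (n_win, n_bins)
    freq = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    times = segment.start_time + (np.arange(n_win) + 0.5) * nperseg / fs
    return SummedSpectrogram(
        window_times=times,
        freq_bins=freq,
        power=power,
        source_segment_id=segment.segment_id,
    )


def reject_artifacts(
    spectrograms: list[SummedSpectrogram], n_mad: float = 3.0
) -> ArtifactMask:
    """Session-level MAD rule on total window power.

    The median and unscaled MAD are pooled over every window of every
    segment in the session; a window is kept iff its summed power lies
    within ``n_mad`` MADs of the session median (deviation exactly at the
    threshold is kept; exclusion is strict).
    """
    if not spectrograms:
        raise InputError("no spectrograms supplied")
    powers = [s.window_power() for s in spectrograms]
    pooled = np.concatenate(powers)
    med = float(np.median(pooled))
    mad = float(np.median(np.abs(pooled - med)))
    keep = {
        s.source_segment_id: np.abs(p - med) <= n_mad * mad
        for s, p in zip(spectrograms, powers)
    }
    return ArtifactMask(keep=keep, session_median_power=med,
                        session_mad_power=mad)


def concatenate_clean(
    segment: TriaxSegment, keep: np.ndarray, window_s: float = 1.0
) -> np.ndarray:
    """Concatenate the kept 1-s windows in time, each linearly detrended.

    Per-window detrending mitigates the temporal discontinuities created
    by removing windows. Returns a (3, m) array; m = 0 when every window
    was rejected (the segment is then excluded from the PSD stage).
    """
    fs = segment.sampling_rate
    nperseg = int(round(fs * window_s))
    n_win = segment.n_samples // nperseg
    keep = np.asarray(keep, dtype=bool)
    if len(keep) != n_win:
        raise InputError(
            f"mask length {len(keep)} does not match {n_win} windows of "
            f"segment {segment.segment_id!r}"
        )
    if not keep.any():
        return np.empty((3, 0))
    frames = segment.channels[:, : n_win * nperseg].reshape(3, n_win, nperseg)
    kept = signal.detrend(frames[:, keep, :], axis=-1, type="linear")
    return kept.reshape(3, -1)


def welch_window_and_nfft(
    sampling_rate: float, window_s: float = 4.0, min_nfft: int = 256
) -> tuple[int, int]:
    """Welch window length in samples and the zero-padded FFT length.

    nfft is the smallest power of two >= the window length (floor 256), so
    the PSD bin spacing is ``sampling_rate / nfft`` — e.g. 0.1506 Hz at
    617 samples/s, 0.2441 Hz at 500 samples/s, 0.2484 Hz at 1017.3.
    """
    nperseg = int(round(sampling_rate * window_s))
    nfft = max(min_nfft, 1 << (nperseg - 1).bit_length())
    return nperseg, nfft


def welch_psd(
    channels: np.ndarray,
    sampling_rate: float,
    window_s: float = 4.0,
    overlap: float = 0.5,
    segment_id: str = "",
    segment_midpoint_time: float = 0.0,
) -> PSDEstimate:
    """Welch PSD with Hamming 4-s windows, axes summed.

    ``channels`` is (3, n) or a 1-D series; the per-axis densities are
    summed so the estimate matches the summed-spectrogram convention.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    nperseg, nfft = welch_window_and_nfft(sampling_rate, window_s)
    if channels.shape[-1] < nperseg:
        raise InputError(
            f"need at least {nperseg} samples ({window_s} s) for Welch PSD, "
            f"got {channels.shape[-1]}"
        )
    freqs, pxx = signal.welch(
        channels,
        fs=sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        nfft=nfft,
        axis=-1,
    )
    return PSDEstimate(
        freqs=freqs,
        power_density=pxx.sum(axis=0),
        nfft=nfft,
        segment_id=segment_id,
        segment_midpoint_time=segment_midpoint_time,
    )


def band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Boolean mask of grid frequencies in the half-open band [lo, hi)."""
    lo, hi = band
    return (freqs >= lo) & (freqs < hi)


def peak_frequency(
    psd: PSDEstimate, search_band: tuple[float, float] = (10.0, 14.0)
) -> float:
    """Frequency of the PSD maximum within the half-open search band.

    Ties break toward the lowest frequency (argmax convention).
    """
    m = band_slice(psd.freqs, search_band)
    if not m.any():
        raise ConfigurationError(
            f"band {search_band} contains no frequency grid points"
        )
    f, p = psd.freqs[m], psd.power_density[m]
    return float(f[np.argmax(p)])


def motion_power_ratio(
    power_row: np.ndarray,
    freq_bins: np.ndarray,
    bands: BandDefinition,
    tremor_band: tuple[float, float] | None = None,
) -> float:
    """Tremor-band power divided by reference-band power for one window.

    Returns NaN (window flagged) when the reference-band power is zero.
    ``tremor_band`` overrides the band in ``bands`` (used for secondary
    bands).
    """
    tband = tremor_band if tremor_band is not None else bands.tremor_band
    num = power_row[band_slice(freq_bins, tband)].sum()
    den = power_row[band_slice(freq_bins, bands.reference_band)].sum()
    if den <= 0:
        return float("nan")
    return float(num / den)


def mpr_series(
    spectrograms: list[SummedSpectrogram],
    mask: ArtifactMask,
    bands: BandDefinition,
    tremor_band: tuple[float, float] | None = None,
) -> MPRSeries:
    """Motion power ratio of every artifact-free window in the session.

    Masked windows carry no MPR value; windows with zero reference power
    (possible only on degenerate input) are dropped with a warning.
    """
    tband = tremor_band if tremor_band is not None else bands.tremor_band
    times, ratios, seg_ids = [], [], []
    for spec in spectrograms:
        keep = mask.keep[spec.source_segment_id]
        num = spec.power[:, band_slice(spec.freq_bins, tband)].sum(axis=1)
        den = spec.power[:, band_slice(spec.freq_bins,
                                       bands.reference_band)].sum(axis=1)
        for w in np.flatnonzero(keep):
            if den[w] <= 0:
                warnings.warn(
                    f"window at t={spec.window_times[w]:.1f}s has zero "
                    "reference-band power; dropped", stacklevel=2)
                continue
            times.append(spec.window_times[w])
            ratios.append(num[w] / den[w])
            seg_ids.append(spec.source_segment_id)
    return MPRSeries(
        window_times=np.asarray(times),
        mpr=np.asarray(ratios),
        bands=bands,
        segment_ids=np.asarray(seg_ids, dtype=object),
    )


def select_tremor_band(
    psds: list[PSDEstimate],
    search_range: tuple[float, float] = (8.0, 16.0),
    half_width: float = 2.0,
    reference_band: tuple[float, float] = (17.0, 21.0),
    baseline_cutoff: float = 900.0,
    floor_factor: float = 3.0,
    secondary_prominence: float = 0.25,
    secondary_search: tuple[float, float] = (4.0, 16.0),
) -> BandDefinition:
    """Designate the tremor band from post-baseline PSD peaks.

    A PSD contributes a vote only when its in-range peak rises above the
    noise floor (peak power >= ``floor_factor`` x the median in-range
    power) and is not saturated at the search-range boundary. The band
    centre is the modal voted peak (votes binned to 0.5 Hz, ties toward
    the lowest); the band is centre +/- ``half_width``, clipped to
    ``search_range``. When no PSD votes, the default 10-14 Hz band is
    returned with ``fallback=True`` and a warning.

    A secondary band is reported when the session-average PSD has a second
    local maximum, at least ``half_width`` away from the primary centre,
    whose power exceeds ``secondary_prominence`` times the primary peak.
    """
    post = [p for p in psds if p.segment_midpoint_time > baseline_cutoff]
    if not post:
        raise InputError("no post-baseline PSDs to select a band from")

    votes = []
    for p in post:
        m = band_slice(p.freqs, search_range)
        f_sub, band_p = p.freqs[m], p.power_density[m]
        pk = float(f_sub[np.argmax(band_p)])
        med = np.median(band_p)
        snr = band_p.max() / med if med > 0 else np.inf
        saturated = pk <= f_sub[0] or pk >= f_sub[-1]
        if snr >= floor_factor and not saturated:
            votes.append(round(pk * 2) / 2)  # 0.5 Hz voting cells

    if not votes:
        warnings.warn(
            "no oscillatory peak above the noise floor; falling back to "
            "the default 10-14 Hz tremor band", stacklevel=2)
        return BandDefinition(tremor_band=(10.0, 14.0),
                              reference_band=reference_band, fallback=True)

    counts = Counter(votes)
    top = max(counts.values())
    center = min(f for f, c in counts.items() if c == top)
    lo = max(search_range[0], center - half_width)
    hi = min(search_range[1], center + half_width)

    # secondary spectral mode on the average PSD (e.g. a low-frequency
    # postural mode coexisting with the main tremor peak)
    secondary = None
    ref = post[0].freqs
    if all(len(p.freqs) == len(ref) and np.allclose(p.freqs, ref)
           for p in post):
        avg = np.mean([p.power_density for p in post], axis=0)
        m = band_slice(ref, secondary_search)
        f_sub, p_sub = ref[m], avg[m]
        idx, _ = signal.find_peaks(p_sub)
        prim_val = p_sub[np.abs(f_sub - center).argmin()]
        cands = [
            (p_sub[i], f_sub[i]) for i in idx
            if abs(f_sub[i] - center) > half_width
            and p_sub[i] >= secondary_prominence * prim_val
        ]
        if cands:
            _, f2 = max(cands)
            secondary = (max(secondary_search[0], f2 - half_width),
                         min(secondary_search[1], f2 + half_width))

    return BandDefinition(tremor_band=(lo, hi), reference_band=reference_band,
                          secondary_band=secondary)
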