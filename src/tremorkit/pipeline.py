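"""End-to-end orchestration: raw session to onset/drift report.

Stages: segmentation of over-long streams, detrend + high-pass, per-second
summed spectrograms, session-level MAD artifact rejection, motion power
ratio with baseline normalization, per-segment signed-rank tests with
Benjamini-Hochberg control and onset extraction, Welch PSDs with peak
tracking and the linear frequency-drift fit. The report is a plain dict
(JSON-serializable) that embeds the full configuration and per-stage
window/segment counts, so any number in it can be traced to parameters.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import onset_stats, preprocessing, spectral
from .config import PipelineConfig
from .exceptions import InputError
from .types import BandDefinition, PSDEstimate, Session

__all__ = ["run_pipeline", "analyze_band"]

log = logging.getLogger("tremorkit")


def _segment_and_preprocess(session: Session, config: PipelineConfig):
    segs = []
    for s in session.segments:
        segs.extend(preprocessing.segment_stream(
            s, max_len_s=config.max_segment_s,
            min_remainder_s=config.min_remainder_s))
    log.info("segmentation: %d raw -> %d analysis segments",
             len(session.segments), len(segs))
    return [
        preprocessing.preprocess_segment(
            s, cutoff_hz=config.highpass_cutoff_hz,
            order=config.filter_order, zero_phase=config.zero_phase,
            apply_highpass=config.apply_highpass)
        for s in segs
    ]


def _session_psds(segs, mask, config: PipelineConfig) -> list[PSDEstimate]:
    psds = []
    for s in segs:
        clean = spectral.concatenate_clean(
            s, mask.keep[s.segment_id],
            window_s=config.spectrogram_window_s)
        nperseg, _ = spectral.welch_window_and_nfft(
            s.sampling_rate, config.welch_window_s)
        if clean.shape[1] < nperseg:
            log.info("segment %s: too little clean data for a PSD",
                     s.segment_id)
            continue
        psds.append(spectral.welch_psd(
            clean, s.sampling_rate, window_s=config.welch_window_s,
            overlap=config.welch_overlap, segment_id=s.segment_id,
            segment_midpoint_time=s.midpoint_time))
    return psds


def analyze_band(
    spectrograms,
    mask,
    bands: BandDefinition,
    config: PipelineConfig,
    tremor_band: tuple[float, float] | None = None,
):
    """MPR -> baseline normalization -> segment stats -> onset for one band."""
    series = spectral.mpr_series(spectrograms, mask, bands,
                                 tremor_band=tremor_band)
    baseline = onset_stats.baseline_median(series,
                                           cutoff_s=config.baseline_cutoff_s)
    series = onset_stats.normalize_mpr(series, baseline)
    seg_stats = onset_stats.segment_stats(
        series, fdr=config.fdr, ci_level=config.ci_level,
        n_boot=config.n_boot, seed=config.bootstrap_seed)
    onset = onset_stats.detect_onset(
        seg_stats, baseline_cutoff_s=config.baseline_cutoff_s)
    return series, baseline, seg_stats, onset


def run_pipeline(
    session: Session,
    config: PipelineConfig | None = None,
    do_drift: bool = True,
) -> dict:
    """Run the full analysis on one session and return the report dict.

    ``do_drift=False`` skips the Welch/peak-tracking/drift stage (and, when
    the tremor band is fixed in the config, all PSD computation).
    """
    config = config or PipelineConfig()
    segs = _segment_and_preprocess(session, config)
    if not segs:
        raise InputError("session contains no analyzable segments")

    spectrograms = [
        spectral.summed_spectrogram(s, window_s=config.spectrogram_window_s)
        for s in segs
    ]
    mask = spectral.reject_artifacts(spectrograms,
                                     n_mad=config.artifact_n_mad)
    log.info("artifact rejection: kept %d of %d windows (median=%.3g, "
             "MAD=%.3g)", mask.n_kept, mask.n_windows,
             mask.session_median_power, mask.session_mad_power)

    need_psds = do_drift or config.tremor_band is None
    psds = _session_psds(segs, mask, config) if need_psds else []

    if config.tremor_band is not None:
        bands = BandDefinition(tremor_band=config.tremor_band,
                               reference_band=config.reference_band)
    else:
        bands = spectral.select_tremor_band(
            psds, search_range=config.band_search_range,
            half_width=config.band_half_width,
            reference_band=config.reference_band,
            baseline_cutoff=config.baseline_cutoff_s)

    series, baseline, seg_stats, onset = analyze_band(
        spectrograms, mask, bands, config)

    report = {
        "subject_id": session.subject_id,
        "dose_mg_per_kg": session.dose_mg_per_kg,
        "config": config.to_dict(),
        "n_segments": len(segs),
        "n_windows": mask.n_windows,
        "n_windows_kept": mask.n_kept,
        "bands": {
            "tremor": list(bands.tremor_band),
            "reference": list(bands.reference_band),
            "secondary": (list(bands.secondary_band)
                          if bands.secondary_band else None),
            "fallback": bands.fallback,
        },
        "baseline": {
            "median_mpr": baseline.baseline_median_mpr,
            "n_windows": baseline.n_baseline_windows,
            "cutoff_s": baseline.baseline_cutoff,
        },
        "segments": [dataclasses.asdict(s) for s in seg_stats],
        "onset_minutes": onset.onset_time,
        "onset_segment_id": onset.onset_segment_id,
    }

    if bands.secondary_band is not None:
        _, _, sec_stats, sec_onset = analyze_band(
            spectrograms, mask, bands, config,
            tremor_band=bands.secondary_band)
        report["secondary_band_onset_minutes"] = sec_onset.onset_time
        report["secondary_band_segments"] = [
            dataclasses.asdict(s) for s in sec_stats]

    if do_drift:
        times_min = np.array([p.segment_midpoint_time / 60.0 for p in psds])
        peaks = np.array([
            spectral.peak_frequency(p, config.peak_search_band)
            for p in psds
        ])
        report["peak_track"] = {
            "times_min": times_min.tolist(),
            "peak_freqs_hz": peaks.tolist(),
        }
        try:
            fit = onset_stats.fit_drift(
                times_min, peaks, cutoff_min=config.drift_cutoff_min,
                band=config.peak_search_band)
            report["drift"] = dataclasses.asdict(fit)
        except InputError as exc:
            log.info("drift fit skipped: %s", exc)
            report["drift"] = None

    return report
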