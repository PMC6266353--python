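"""EEG conditioning: band-pass/notch filtering, downsampling, segment
extraction with artifact rejection, and ensemble averaging.

The chain mirrors the speller protocol: a 4th-order Butterworth band-pass
between 0.1 and 10 Hz plus a 50 Hz notch, downsampling to 16 Hz, 1-s
segments cut at each stimulus onset with rejection of windows whose
peak-to-peak range exceeds 70 uV, and coherent point-to-point averaging of
same-stimulus segments.  All filters are applied forward-backward
(zero-phase) so waveform latencies — which every downstream feature is
sensitive to — are not shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .synth import EEGStream, StimulusSchedule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass / notch / resampling parameters."""

    band_low: float = 0.1       #: Hz, high-pass edge
    band_high: float = 10.0     #: Hz, low-pass edge
    order: int = 4              #: Butterworth order
    notch_freq: float = 50.0    #: Hz, line-noise notch
    notch_q: float = 30.0       #: notch quality factor
    target_fs: float = 16.0     #: Hz, decoding sample rate

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class Segment:
    """One 1-s multichannel window cut at a stimulus onset."""

    data: np.ndarray            #: (channels, n) with n = fs * 1 s
    label: bool
    stimulus_id: int
    trial_index: int
    onset: float


@dataclass
class AveragedSegment:
    """Point-to-point mean of same-stimulus segments within a trial."""

    data: np.ndarray
    stimulus_id: int
    n_averaged: int

    def __post_init__(self) -> None:
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")


def bandpass_notch(stream: EEGStream, spec: FilterSpec | None = None) -> EEGStream:
    """Zero-phase band-pass then notch filtering, per channel.

    Both filters run forward-backward (``sosfiltfilt`` / ``filtfilt``), so
    the magnitude response is applied twice and the phase response cancels.
    Output length equals input length.
    """
    spec = spec or FilterSpec()
    nyq = stream.fs / 2.0
    if spec.band_high >= nyq:
        raise ValueError(
            f"band edge {spec.band_high} Hz is not below Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(
        spec.order, [spec.band_low, spec.band_high], btype="bandpass", fs=stream.fs, output="sos"
    )
    # even-symmetric padding spanning several high-pass time constants keeps
    # the very low 0.1 Hz corner from ringing off the segment edges
    padlen = int(min(stream.n_samples - 1, 3.0 * stream.fs / spec.band_low))
    data = signal.sosfiltfilt(sos, stream.data, axis=1, padtype="even", padlen=padlen)
    if 0 < spec.notch_freq < nyq:
        b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=stream.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return EEGStream(
        data=data, fs=stream.fs, channel_names=stream.channel_names, schedule=stream.schedule
    )


def resample(stream: EEGStream, target_fs: float) -> EEGStream:
    """Anti-aliased rational-ratio downsampling (e.g. 250 -> 16 Hz = up 8 / down 125).

    Uses polyphase filtering, so the result is bit-reproducible and
    alias-free.  Stimulus onsets live in the schedule as seconds and are
    not interpolated; segmentation snaps them to the nearest sample of the
    new rate.  Upsampling is out of scope and rejected.
    """
    if target_fs >= stream.fs:
        raise ValueError("resample only downsamples: target_fs must be below fs")
    ratio = Fraction(target_fs / stream.fs).limit_denominator(10000)
    data = signal.resample_poly(
        stream.data, ratio.numerator, ratio.denominator, axis=1, padtype="mean"
    )
    expected = int(round(stream.n_samples * target_fs / stream.fs))
    data = data[:, :expected]
    return EEGStream(
        data=data, fs=target_fs, channel_names=stream.channel_names, schedule=stream.schedule
    )


def preprocess_session(stream: EEGStream, spec: FilterSpec | None = None) -> EEGStream:
    """Full conditioning chain: band-pass + notch, then downsample."""
    spec = spec or FilterSpec()
    filtered = bandpass_notch(stream, spec)
    if spec.target_fs < stream.fs:
        filtered = resample(filtered, spec.target_fs)
    return filtered


def extract_segments(
    stream: EEGStream,
    schedule: StimulusSchedule | None = None,
    reject_uv: float = 70.0,
) -> list[Segment]:
    """Cut one 1-s window per stimulus event, dropping artifact windows.

    The window is ``[onset, onset + 1 s)`` with the onset snapped to the
    nearest sample.  A segment is rejected when any channel's peak-to-peak
    range within the window exceeds ``reject_uv`` (pass ``np.inf`` to keep
    everything).  Events whose window would run past the stream end are
    skipped with a warning.
    """
    schedule = schedule or stream.schedule
    if schedule is None:
        raise ValueError("no stimulus schedule available")
    n = int(round(stream.fs))
    segments: list[Segment] = []
    n_rejected = n_skipped = 0
    for ev in schedule.events:
        start = int(round(ev.onset * stream.fs))
        if start + n > stream.n_samples:
            logger.warning("segment at %.3f s runs past stream end; skipped", ev.onset)
            n_skipped += 1
            continue
        window = stream.data[:, start : start + n]
        if np.ptp(window, axis=1).max() > reject_uv:
            n_rejected += 1
            continue
        segments.append(
            Segment(
                data=window.copy(),
                label=ev.label,
                stimulus_id=ev.stimulus_id,
                trial_index=ev.trial_index,
                onset=ev.onset,
            )
        )
    logger.info(
        "extracted %d segments (%d rejected as artifacts, %d out of range)",
        len(segments), n_rejected, n_skipped,
    )
    return segments


def ensemble_average(
    segments: list[Segment],
    stimulus_id: int,
    n_sequences: int | None = None,
) -> AveragedSegment:
    """Coherent point-to-point mean of the segments for one stimulus id.

    Averages the first ``n_sequences`` matching segments (all of them when
    ``None``), per channel per sample.  Averaging N time-locked segments
    shrinks zero-mean noise variance by 1/N while the time-locked ERP is
    preserved, which is what makes single-channel waveform decoding viable.
    """
    matching = [s for s in segments if s.stimulus_id == stimulus_id]
    if n_sequences is not None:
        matching = matching[:n_sequences]
    if not matching:
        raise ValueError(f"no segments with stimulus_id {stimulus_id}")
    data = np.mean([s.data for s in matching], axis=0)
    return AveragedSegment(data=data, stimulus_id=stimulus_id, n_averaged=len(matching))
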