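"""Pseudo-real P300 speller session generation.

A visual P300 speller flashes the 6 rows and 6 columns of a 6x6 character
matrix in random order.  Each full sweep of the 12 intensifications is one
*sequence*; a *trial* (one spelled letter) comprises ``n_sequences``
sequences.  Flashes of the row and the column holding the attended letter
are *targets* and elicit a P300 event-related potential (ERP) roughly
300-400 ms after stimulus onset.

This module builds controlled "pseudo-real" sessions: a stimulus schedule,
a synthetic background EEG stream with no ERP content, and the additive
superposition of ERP templates at the target-stimulus onsets.  Because the
injected waveform, its timing and its amplitude are known exactly, the
sessions provide ground truth for benchmarking waveform decoders under
three regimes: clean time-locked superposition, uniformly jittered
superposition latency, and random attenuation of the P3b component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import windows

logger = logging.getLogger(__name__)

# --- speller matrix ---------------------------------------------------------

#: 6x6 speller layout, row-major A-Z then 0-9.  The source protocol never
#: prints its matrix; this layout is the package convention.
SPELLER_LAYOUT: tuple[str, ...] = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")

ROW_IDS = tuple(range(1, 7))      #: stimulus ids of row flashes
COL_IDS = tuple(range(7, 13))     #: stimulus ids of column flashes

#: default electrode montage (10-20 positions used by the speller protocol)
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")

#: relative P300 amplitude per montage position (parieto-central maximum)
DEFAULT_CHANNEL_GAINS = (0.55, 0.9, 1.0, 0.5, 0.8, 0.8, 0.65, 0.6)


def letter_position(letter: str) -> tuple[int, int]:
    """Return ``(row_id, col_id)`` of *letter*: row in 1-6, column in 7-12."""
    letter = letter.upper()
    if letter not in SPELLER_LAYOUT:
        raise ValueError(f"letter {letter!r} is not in the 6x6 speller matrix")
    idx = SPELLER_LAYOUT.index(letter)
    return idx // 6 + 1, idx % 6 + 7


def matrix_letter(row_id: int, col_id: int) -> str:
    """Return the character at matrix cell ``(row_id, col_id)``."""
    if row_id not in ROW_IDS:
        raise ValueError(f"row id must be in 1..6, got {row_id}")
    if col_id not in COL_IDS:
        raise ValueError(f"column id must be in 7..12, got {col_id}")
    return SPELLER_LAYOUT[(row_id - 1) * 6 + (col_id - 7)]


# --- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class SpellerTiming:
    """Stimulation timing of the speller protocol (seconds).

    Defaults follow the benchmark protocol: 0.125 s flash + 0.125 s
    inter-stimulus interval (4 Hz flash rate), 20 s initial and
    inter-trial pauses.
    """

    flash_duration: float = 0.125
    isi: float = 0.125
    initial_pause: float = 20.0
    inter_trial_pause: float = 20.0

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony: flash + ISI."""
        return self.flash_duration + self.isi

    @property
    def flash_rate(self) -> float:
        """Flashes per second on screen."""
        return 1.0 / self.soa


@dataclass(frozen=True)
class StimulusEvent:
    onset: float            #: seconds from session start
    stimulus_id: int        #: 1-6 rows, 7-12 columns
    label: bool             #: True when the flash covers the target letter
    trial_index: int

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.stimulus_id not in range(1, 13):
            raise ValueError(f"stimulus_id must be in 1..12, got {self.stimulus_id}")


@dataclass(frozen=True)
class TrialSchedule:
    target: str
    events: tuple[StimulusEvent, ...]


@dataclass(frozen=True)
class StimulusSchedule:
    """Timed row/column intensifications for a whole session."""

    trials: tuple[TrialSchedule, ...]
    timing: SpellerTiming
    n_sequences: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def events(self) -> tuple[StimulusEvent, ...]:
        return tuple(ev for trial in self.trials for ev in trial.events)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(trial.target for trial in self.trials)

    @property
    def duration(self) -> float:
        """Seconds needed to hold every event plus its 1-s analysis window."""
        return max(ev.onset for ev in self.events) + 1.0 + self.timing.isi


@dataclass
class ErpTemplate:
    """A 1-s multichannel ERP waveform in microvolts."""

    samples: np.ndarray     #: (channels, T) with T = fs * 1 s
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("template samples must be 2-D (channels, T)")
        if self.samples.shape[1] != int(round(self.fs)):
            raise ValueError(
                f"template must be 1 s long: expected {int(round(self.fs))} "
                f"samples at {self.fs} Hz, got {self.samples.shape[1]}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("template contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class EEGStream:
    """Multichannel EEG (microvolts) with an optional stimulus schedule."""

    data: np.ndarray        #: (channels, samples)
    fs: float
    channel_names: tuple[str, ...]
    schedule: StimulusSchedule | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels, samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class NoiseConfig:
    """Controlled degradations applied during template superposition.

    ``latency_*`` bound the uniform superposition lag (seconds) of the
    latency-jitter regime; ``gain_*`` bound the uniform attenuation gain of
    the amplitude-noise regime.  ``p3b_window`` delimits the P3b component
    relative to stimulus onset, in milliseconds; the attenuated copy is
    tapered by a Gaussian window whose standard deviation is
    ``support / gauss_window_shape`` so it vanishes at the window edges.
    """

    latency_low: float = 0.0
    latency_high: float = 0.4
    gain_low: float = 0.0
    gain_high: float = 1.0
    p3b_window: tuple[float, float] = (148.0, 996.0)
    gauss_window_shape: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.latency_low <= self.latency_high:
            raise ValueError("latency bounds must satisfy 0 <= low <= high")
        if not 0.0 <= self.gain_low <= self.gain_high <= 1.0:
            raise ValueError("gain bounds must satisfy 0 <= low <= high <= 1")
        if self.p3b_window[0] >= self.p3b_window[1]:
            raise ValueError("p3b window start must precede its end")
        if self.gauss_window_shape <= 0:
            raise ValueError("gauss_window_shape must be positive")


# --- operations -------------------------------------------------------------


def _as_rng(seed: int | Generator | SeedSequence) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


def generate_schedule(
    n_trials: int,
    n_sequences: int,
    targets: str | list[str] | tuple[str, ...],
    timing: SpellerTiming | None = None,
    seed: int | Generator = 0,
) -> StimulusSchedule:
    """Build the randomized row/column intensification schedule.

    Each trial holds ``n_sequences`` sequences; each sequence flashes every
    stimulus id 1-12 exactly once in random order, with onsets spaced by
    the stimulus-onset asynchrony.  Exactly ``2 * n_sequences`` events per
    trial are labeled True (the target's row and column).
    """
    if n_trials < 1 or n_sequences < 1:
        raise ValueError("n_trials and n_sequences must be >= 1")
    targets = [t.upper() for t in targets]
    if len(targets) != n_trials:
        raise ValueError(f"need {n_trials} target letters, got {len(targets)}")
    timing = timing or SpellerTiming()
    rng = _as_rng(seed)

    trials = []
    trial_duration = 12 * n_sequences * timing.soa
    for t, target in enumerate(targets):
        row_id, col_id = letter_position(target)
        t0 = timing.initial_pause + t * (trial_duration + timing.inter_trial_pause)
        events = []
        for s in range(n_sequences):
            order = rng.permutation(12) + 1
            for j, sid in enumerate(order):
                onset = t0 + (s * 12 + j) * timing.soa
                events.append(
                    StimulusEvent(
                        onset=onset,
                        stimulus_id=int(sid),
                        label=sid in (row_id, col_id),
                        trial_index=t,
                    )
                )
        trials.append(TrialSchedule(target=target, events=tuple(events)))
    return StimulusSchedule(trials=tuple(trials), timing=timing, n_sequences=n_sequences)


def synth_background(
    duration: float,
    n_channels: int,
    fs: float,
    pink_rms: float = 8.0,
    alpha_amp: float = 10.0,
    alpha_freq: float = 10.0,
    seed: int | Generator = 0,
) -> EEGStream:
    """Synthesize ERP-free background EEG.

    The model is a 1/f-shaped (pink) Gaussian process plus a 10 Hz
    alpha-band sinusoid with an independent random phase per channel,
    scaled so excursions stay within roughly +/-30 uV.  It reproduces the
    gross EEG amplitude spectrum without any stimulus-locked content,
    standing in for passively recorded speller EEG in which the viewer
    attends no letter.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = _as_rng(seed)
    n = int(round(duration * fs))

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])        # power ~ 1/f, no DC

    white = rng.standard_normal((n_channels, n))
    spectrum = np.fft.rfft(white, axis=1) * shaping
    pink = np.fft.irfft(spectrum, n=n, axis=1)
    pink *= pink_rms / pink.std(axis=1, keepdims=True)

    t = np.arange(n) / fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_channels)
    alpha = alpha_amp * np.sin(2.0 * np.pi * alpha_freq * t[None, :] + phases[:, None])

    names = tuple(
        DEFAULT_CHANNELS[i] if i < len(DEFAULT_CHANNELS) else f"ch{i}"
        for i in range(n_channels)
    )
    return EEGStream(data=pink + alpha, fs=fs, channel_names=names)


def make_template_pool(
    n_templates: int = 70,
    n_channels: int = 8,
    fs: float = 250.0,
    channel_gains: tuple[float, ...] | None = None,
    peak_amplitude: float = 9.0,
    seed: int | Generator = 0,
) -> list[ErpTemplate]:
    """Synthesize a pool of 1-s P300 ERP templates.

    Each template is a canonical target-locked waveform: a positive P3b
    deflection (Gaussian bump peaking near 350 ms, ~9 uV at the strongest
    channel) preceded by a small N2 negativity near 200 ms, scaled per
    channel by a parieto-central topography.  Per-template perturbations
    (peak latency, amplitude, width) emulate single-extraction variability
    of real averaged templates.  The default pool size of 70 matches two
    target templates from each of 35 trials.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    rng = _as_rng(seed)
    gains = channel_gains or DEFAULT_CHANNEL_GAINS
    gains = np.asarray(
        [gains[i] if i < len(gains) else 0.6 for i in range(n_channels)], dtype=float
    )
    n = int(round(fs))
    t = np.arange(n) / fs

    pool = []
    for _ in range(n_templates):
        p3_lat = 0.35 + rng.normal(0.0, 0.015)
        p3_sig = 0.09 * rng.uniform(0.9, 1.1)
        n2_lat = 0.20 + rng.normal(0.0, 0.010)
        amp = peak_amplitude * rng.uniform(0.85, 1.15)
        wave = amp * np.exp(-0.5 * ((t - p3_lat) / p3_sig) ** 2)
        wave -= 0.28 * amp * np.exp(-0.5 * ((t - n2_lat) / 0.035) ** 2)
        pool.append(ErpTemplate(samples=gains[:, None] * wave[None, :], fs=fs))
    return pool


def add_latency(
    onsets: np.ndarray,
    config: NoiseConfig,
    seed: int | Generator = 0,
) -> np.ndarray:
    """Jitter superposition onsets by independent uniform lags.

    Each onset is shifted by a draw from ``U(latency_low, latency_high)``.
    Only the waveform-injection positions move; the stimulus markers used
    later for segmentation stay put, which is exactly what degrades the
    time-locking of the ensemble average.
    """
    if config.latency_high >= 1.0:
        raise ValueError("latency bound must be below the 1-s segment length")
    rng = _as_rng(seed)
    onsets = np.asarray(onsets, dtype=float)
    return onsets + rng.uniform(config.latency_low, config.latency_high, size=onsets.shape)


def attenuate_p3b(
    template: ErpTemplate,
    config: NoiseConfig,
    seed: int | Generator = 0,
) -> ErpTemplate:
    """Randomly attenuate the P3b component of a template.

    A copy of the samples inside the P3b window (148-996 ms after onset by
    default), tapered by a Gaussian window spanning the same support, is
    scaled by a gain drawn from ``U(gain_low, gain_high)`` and subtracted
    from the template.  The taper is ~0 at the window edges, so no
    amplitude discontinuity is introduced; samples outside the window are
    untouched.
    """
    rng = _as_rng(seed)
    fs = template.fs
    a = int(round(config.p3b_window[0] * 1e-3 * fs))
    b = int(round(config.p3b_window[1] * 1e-3 * fs))
    if a < 0 or b > template.samples.shape[1]:
        raise ValueError("P3b window falls outside the 1-s template")
    support = b - a
    gwin = windows.gaussian(support, std=support / config.gauss_window_shape)
    gain = rng.uniform(config.gain_low, config.gain_high)
    samples = template.samples.copy()
    samples[:, a:b] -= gain * gwin[None, :] * template.samples[:, a:b]
    return replace(template, samples=samples)


def superimpose_template(
    stream: EEGStream,
    schedule: StimulusSchedule,
    templates: list[ErpTemplate],
    seed: int | Generator = 0,
    noise: NoiseConfig | None = None,
    latency_noise: bool = False,
    amplitude_noise: bool = False,
) -> EEGStream:
    """Add one randomly chosen ERP template at every True-labeled event.

    The 1-s window starting at each target onset becomes background plus
    template, point to point; non-target windows are untouched.  With
    ``latency_noise`` the injection point of each template is lagged by an
    independent uniform draw while markers stay fixed; with
    ``amplitude_noise`` each injected template first has its P3b component
    randomly attenuated.
    """
    if not templates:
        raise ValueError("template pool is empty")
    for tpl in templates:
        if tpl.fs != stream.fs:
            raise ValueError("template and stream sampling rates differ")
        if tpl.n_channels != stream.n_channels:
            raise ValueError("template and stream channel counts differ")
    noise = noise or NoiseConfig()
    rng = _as_rng(seed)

    data = stream.data.copy()
    true_events = [ev for ev in schedule.events if ev.label]
    onsets = np.array([ev.onset for ev in true_events])
    if latency_noise:
        onsets = add_latency(onsets, noise, rng)
    n_injected = 0
    for onset, ev in zip(onsets, true_events):
        tpl = templates[int(rng.integers(len(templates)))]
        if amplitude_noise:
            tpl = attenuate_p3b(tpl, noise, rng)
        start = int(round(onset * stream.fs))
        stop = min(start + tpl.samples.shape[1], data.shape[1])
        if start >= data.shape[1]:
            logger.warning("event onset %.3f s beyond stream end; skipped", onset)
            continue
        data[:, start:stop] += tpl.samples[:, : stop - start]
        n_injected += 1
    logger.info("superimposed %d templates on %d target events", n_injected, len(true_events))
    return EEGStream(
        data=data, fs=stream.fs, channel_names=stream.channel_names, schedule=schedule
    )


def simulate_session(
    n_trials: int = 35,
    n_sequences: int = 10,
    n_channels: int = 8,
    fs: float = 250.0,
    targets: str | list[str] | None = None,
    timing: SpellerTiming | None = None,
    experiment: int = 1,
    modality: str = "active",
    noise: NoiseConfig | None = None,
    templates: list[ErpTemplate] | None = None,
    n_templates: int = 70,
    pink_rms: float = 8.0,
    alpha_amp: float = 10.0,
    seed: int = 0,
) -> EEGStream:
    """Generate a complete pseudo-real speller session.

    Draws a schedule, synthesizes background EEG, builds (or accepts) an
    ERP template pool and superimposes templates at target onsets under
    the regime selected by ``experiment``: 1 = exact time-locked
    superposition, 2 = uniform latency jitter of the injected waveform,
    3 = random P3b attenuation.  ``modality`` is provenance metadata
    ("passive": templates nominally foreign to the background subject;
    "active": own templates) — with a synthetic pool the two coincide.

    One session-level seed drives independent substreams for the schedule,
    the background, the pool, the target letters and the superposition, so
    identical arguments reproduce the session bit for bit.
    """
    if experiment not in (1, 2, 3):
        raise ValueError("experiment must be 1, 2 or 3")
    if modality not in ("passive", "active"):
        raise ValueError("modality must be 'passive' or 'active'")
    ss = SeedSequence(seed)
    s_sched, s_bg, s_pool, s_targets, s_super = (default_rng(c) for c in ss.spawn(5))

    if targets is None:
        targets = [SPELLER_LAYOUT[i] for i in s_targets.integers(0, 36, size=n_trials)]
    schedule = generate_schedule(n_trials, n_sequences, targets, timing, seed=s_sched)
    background = synth_background(
        duration=np.ceil(schedule.duration) + 1.0,
        n_channels=n_channels,
        fs=fs,
        pink_rms=pink_rms,
        alpha_amp=alpha_amp,
        seed=s_bg,
    )
    if templates is None:
        templates = make_template_pool(
            n_templates=n_templates, n_channels=n_channels, fs=fs, seed=s_pool
        )
    return superimpose_template(
        background,
        schedule,
        templates,
        seed=s_super,
        noise=noise,
        latency_noise=experiment == 2,
        amplitude_noise=experiment == 3,
    )
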