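"""Benchmark harness: cross-validated letter-identification experiments.

Three experiments probe the waveform decoders on pseudo-real sessions:

1. clean time-locked superposition (baseline identification performance);
2. uniform latency jitter ``U(0, 0.4)`` s of the injected waveform, which
   corrupts the time-locking exploited by ensemble averaging;
3. random attenuation of the template's P3b component, which perturbs
   peak amplitude but not timing.

Each run repeatedly scrambles the spelled letters (the internal structure
of every trial is preserved), assigns the first ``split[0]`` trials to
template-dictionary building and the remaining ``split[1]`` to testing,
and measures per-channel letter accuracy as a function of the number of
intensification sequences entering the ensemble average.  Averaged
segments and their features depend only on the trial, so they are
computed once and shared across repeats.

An optional runner replays the same offline simulation on externally
supplied P300 matrix-speller competition recordings (240 Hz, 6x6 matrix,
15 sequences, first 42 letters training / remaining 31 testing).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.io import loadmat, savemat

from .classify import (
    Prediction,
    SpellerMatrix,
    TemplateDictionary,
    knn_select,
    mp1_select,
    svm_select,
    train_linear_margin,
)
from .features import (
    FeatureConfig,
    Method,
    build_mp1_dictionary,
    build_mp2_dictionary,
    extract_feature,
)
from .preprocess import FilterSpec, Segment, extract_segments, preprocess_session
from .synth import (
    COL_IDS,
    ROW_IDS,
    SPELLER_LAYOUT,
    EEGStream,
    NoiseConfig,
    SpellerTiming,
    StimulusEvent,
    StimulusSchedule,
    TrialSchedule,
    letter_position,
    simulate_session,
)

logger = logging.getLogger(__name__)

#: methods evaluated by default; RAW is the linear-margin SVM control
DEFAULT_METHODS = (Method.MP1, Method.MP2, Method.PE, Method.SHCC, Method.SIFT, Method.RAW)


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmark run: generation regime, methods, CV layout."""

    experiment: int = 1
    modality: str = "active"
    methods: tuple[Method | str, ...] = DEFAULT_METHODS
    n_repeats: int = 100
    split: tuple[int, int] = (15, 20)
    sequence_range: tuple[int, ...] = tuple(range(1, 11))
    k: int = 3
    mp_atoms: int = 5
    reject_uv: float = 70.0
    feature_cfg: FeatureConfig = field(default_factory=FeatureConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    # session generation (used by run_experiment)
    n_trials: int = 35
    n_sequences: int = 10
    n_channels: int = 8
    fs: float = 250.0
    pink_rms: float = 8.0
    alpha_amp: float = 10.0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if min(self.split) < 1:
            raise ValueError("both split sizes must be >= 1")
        object.__setattr__(self, "methods", tuple(Method(m) for m in self.methods))


class _FeatureCache:
    """Per-trial averaged segments and features, shared across CV repeats.

    Averaged candidate segments and their features depend only on
    ``(trial, stimulus_id, n_sequences, channel)``, never on the split, so
    one pass over the session serves every repeat.  A constant (flat)
    averaged segment carries no waveform and cannot hold a P300; it is
    excluded from candidacy for every method.
    """

    def __init__(
        self,
        segments: list[Segment],
        schedule: StimulusSchedule,
        channels: tuple[str, ...],
        methods: tuple[Method, ...],
        cfg: ExperimentConfig,
    ) -> None:
        self.schedule = schedule
        self.channels = channels
        self.methods = methods
        self.cfg = cfg
        self.template_n_seq = schedule.n_sequences
        self.n_seq_values = sorted(set(cfg.sequence_range) | {self.template_n_seq})

        by_trial_sid: dict[tuple[int, int], list[np.ndarray]] = {}
        for s in sorted(segments, key=lambda s: s.onset):
            by_trial_sid.setdefault((s.trial_index, s.stimulus_id), []).append(s.data)

        self.avg: dict[tuple[int, int, int], np.ndarray | None] = {}
        for (t, sid), datas in by_trial_sid.items():
            stack = np.stack(datas)                      # (n_reps, C, n)
            csum = np.cumsum(stack, axis=0)
            for n_seq in self.n_seq_values:
                m = min(n_seq, len(datas))
                self.avg[(t, sid, n_seq)] = csum[m - 1] / m

        mp2_dict = None
        needs_mp2 = Method.MP2 in methods
        sample_len = next(iter(by_trial_sid.values()))[0].shape[1] if by_trial_sid else 0
        if needs_mp2 and sample_len:
            mp2_dict = build_mp2_dictionary(sample_len)
        self.mp2_dict = mp2_dict

        # feat[(method, ch, t, sid, n_seq)] -> vector or None (degenerate/missing)
        self.feat: dict[tuple, np.ndarray | None] = {}
        feature_methods = [m for m in methods if m is not Method.MP1]
        for (t, sid, n_seq), data in self.avg.items():
            for ch in range(len(channels)):
                x = data[ch]
                degenerate = np.ptp(x) == 0
                for m in feature_methods:
                    key = (m, ch, t, sid, n_seq)
                    self.feat[key] = (
                        None if degenerate else extract_feature(x, m, cfg.feature_cfg, mp2_dict)
                    )

    def signal(self, t: int, sid: int, n_seq: int, ch: int) -> np.ndarray | None:
        data = self.avg.get((t, sid, n_seq))
        if data is None:
            return None
        x = data[ch]
        return None if np.ptp(x) == 0 else x

    def feature(self, method: Method, ch: int, t: int, sid: int, n_seq: int):
        return self.feat.get((method, ch, t, sid, n_seq))

    def target_ids(self, t: int) -> tuple[int, int]:
        return letter_position(self.schedule.trials[t].target)

    def template_pool(self, method: Method, ch: int, train_trials) -> list[np.ndarray]:
        """Two target templates (row, column) per training trial."""
        pool = []
        for t in train_trials:
            for sid in self.target_ids(t):
                if method is Method.MP1:
                    vec = self.signal(t, sid, self.template_n_seq, ch)
                else:
                    vec = self.feature(method, ch, t, sid, self.template_n_seq)
                if vec is None:
                    raise ValueError(
                        f"trial {t} stimulus {sid}: target template missing or degenerate"
                    )
                pool.append(vec)
        return pool


def _evaluate_split(
    cache: _FeatureCache,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    cfg: ExperimentConfig,
) -> dict[tuple[Method, str, int], int]:
    """Letter-correct counts per (method, channel, n_sequences) for one split."""
    n_channels = len(cache.channels)
    dictionaries: dict[tuple[Method, int], TemplateDictionary] = {}
    svms: dict[int, object] = {}
    for ch in range(n_channels):
        for m in cfg.methods:
            pool = cache.template_pool(m, ch, train_trials)
            if m is Method.MP1:
                dictionaries[(m, ch)] = TemplateDictionary(
                    method=m,
                    channel=cache.channels[ch],
                    mp_dictionary=build_mp1_dictionary(pool),
                    k=cfg.k,
                )
            elif m is Method.RAW:
                X, y = [], []
                for t in train_trials:
                    targets = set(cache.target_ids(t))
                    for sid in range(1, 13):
                        f = cache.feature(m, ch, t, sid, cache.template_n_seq)
                        if f is not None:
                            X.append(f)
                            y.append(int(sid in targets))
                svms[ch] = train_linear_margin(np.vstack(X), np.array(y))
            else:
                dictionaries[(m, ch)] = TemplateDictionary(
                    method=m,
                    channel=cache.channels[ch],
                    templates=np.vstack(pool),
                    k=min(cfg.k, 2 * len(train_trials)),
                )

    correct: dict[tuple[Method, str, int], int] = {
        (m, cache.channels[ch], n_seq): 0
        for m in cfg.methods
        for ch in range(n_channels)
        for n_seq in cfg.sequence_range
    }
    for t in test_trials:
        target = cache.schedule.trials[t].target
        for n_seq in cfg.sequence_range:
            for ch in range(n_channels):
                for m in cfg.methods:
                    if m is Method.MP1:
                        rows = {u: v for u in ROW_IDS if (v := cache.signal(t, u, n_seq, ch)) is not None}
                        cols = {u: v for u in COL_IDS if (v := cache.signal(t, u, n_seq, ch)) is not None}
                        if not rows or not cols:
                            continue
                        row = mp1_select(rows, dictionaries[(m, ch)], cfg.mp_atoms)
                        col = mp1_select(cols, dictionaries[(m, ch)], cfg.mp_atoms)
                    else:
                        rows = {u: v for u in ROW_IDS if (v := cache.feature(m, ch, t, u, n_seq)) is not None}
                        cols = {u: v for u in COL_IDS if (v := cache.feature(m, ch, t, u, n_seq)) is not None}
                        if not rows or not cols:
                            continue
                        if m is Method.RAW:
                            row = svm_select(rows, svms[ch])
                            col = svm_select(cols, svms[ch])
                        else:
                            row = knn_select(rows, dictionaries[(m, ch)])
                            col = knn_select(cols, dictionaries[(m, ch)])
                    letter = SpellerMatrix().letter(row, col)
                    if letter == target:
                        correct[(m, cache.channels[ch], n_seq)] += 1
    return correct


def crossvalidate(
    session: EEGStream,
    cfg: ExperimentConfig,
    filter_spec: FilterSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Repeated scrambled-split cross-validation of letter identification.

    Returns the performance curve: one row per (method, channel,
    n_sequences) with the mean letter accuracy (fraction in [0, 1]) over
    ``n_repeats`` random splits of ``split[0]`` dictionary-building and
    ``split[1]`` test trials.
    """
    schedule = session.schedule
    if schedule is None:
        raise ValueError("session carries no stimulus schedule")
    n_train, n_test = cfg.split
    if n_train + n_test > schedule.n_trials:
        raise ValueError(
            f"split {cfg.split} exceeds the {schedule.n_trials} trials available"
        )
    processed = preprocess_session(session, filter_spec)
    segments = extract_segments(processed, schedule, reject_uv=cfg.reject_uv)
    cache = _FeatureCache(segments, schedule, processed.channel_names, cfg.methods, cfg)

    rng = default_rng(cfg.seed if seed is None else seed)
    totals: dict[tuple[Method, str, int], int] = {}
    for _ in range(cfg.n_repeats):
        perm = rng.permutation(schedule.n_trials)
        counts = _evaluate_split(cache, perm[:n_train], perm[n_train : n_train + n_test], cfg)
        for key, c in counts.items():
            totals[key] = totals.get(key, 0) + c

    denom = cfg.n_repeats * n_test
    records = [
        {"method": m.value, "channel": chn, "n_sequences": n_seq, "accuracy": c / denom}
        for (m, chn, n_seq), c in totals.items()
    ]
    return pd.DataFrame.from_records(records).sort_values(
        ["method", "channel", "n_sequences"], ignore_index=True
    )


def run_experiment(cfg: ExperimentConfig, filter_spec: FilterSpec | None = None) -> pd.DataFrame:
    """Simulate a session under ``cfg`` and cross-validate it."""
    ss = SeedSequence(cfg.seed).spawn(2)
    session = simulate_session(
        n_trials=cfg.n_trials,
        n_sequences=cfg.n_sequences,
        n_channels=cfg.n_channels,
        fs=cfg.fs,
        experiment=cfg.experiment,
        modality=cfg.modality,
        noise=cfg.noise,
        pink_rms=cfg.pink_rms,
        alpha_amp=cfg.alpha_amp,
        seed=cfg.seed,
    )
    return crossvalidate(session, cfg, filter_spec, seed=int(ss[1].generate_state(1)[0] % 2**31))


def best_worst_channels(curve: pd.DataFrame) -> tuple[str, str]:
    """Best- and worst-performing channels at the largest sequence count.

    Accuracy is averaged over methods at the maximum ``n_sequences`` in
    the curve; ties resolve to the channel appearing first.
    """
    if curve.empty:
        raise ValueError("empty performance curve")
    at_max = curve[curve["n_sequences"] == curve["n_sequences"].max()]
    order = list(dict.fromkeys(curve["channel"]))
    means = at_max.groupby("channel")["accuracy"].mean()
    best = max(order, key=lambda c: (means[c], -order.index(c)))
    worst = min(order, key=lambda c: (means[c], order.index(c)))
    return best, worst


# --- optional competition-dataset runner ------------------------------------

#: the competition's 6x6 layout; codes 1-6 flash columns, 7-12 flash rows
COMPETITION_LAYOUT = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ123456789_")


@dataclass
class CompetitionData:
    """Offline matrix-speller recording in the competition file layout."""

    signal: np.ndarray          #: (letters, samples, channels), uV
    stimulus_code: np.ndarray   #: (letters, samples), 0 or 1-12
    stimulus_type: np.ndarray   #: (letters, samples), 1 at target flashes
    target_chars: str
    fs: float = 240.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.signal.ndim != 3:
            raise ValueError("signal must be (letters, samples, channels)")
        if len(self.target_chars) != self.signal.shape[0]:
            raise ValueError("one target character per letter trial is required")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.signal.shape[2]))


def _competition_char_to_layout(char: str) -> str:
    """Map a competition-matrix character onto the package's 6x6 layout."""
    idx = COMPETITION_LAYOUT.index(char.upper())
    return SPELLER_LAYOUT[idx]


def load_competition_iib(path: str) -> CompetitionData:
    """Read a competition recording from a MATLAB container.

    Expects the keys ``Signal``, ``StimulusCode``, ``StimulusType`` and
    ``TargetChar``.  Files are never downloaded; a missing or malformed
    file raises with a clear message.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"competition data file not found: {path}")
    try:
        mat = loadmat(path)
    except Exception as exc:  # pragma: no cover - corrupt input
        raise ValueError(f"cannot parse competition file {path}: {exc}") from exc
    missing = [k for k in ("Signal", "StimulusCode", "StimulusType", "TargetChar") if k not in mat]
    if missing:
        raise ValueError(f"competition file {path} lacks required keys: {missing}")
    target = mat["TargetChar"]
    target_chars = "".join(str(c) for c in np.ravel(target).astype(str))
    return CompetitionData(
        signal=np.asarray(mat["Signal"], dtype=float),
        stimulus_code=np.asarray(mat["StimulusCode"], dtype=int).reshape(mat["Signal"].shape[:2]),
        stimulus_type=np.asarray(mat["StimulusType"], dtype=int).reshape(mat["Signal"].shape[:2]),
        target_chars=target_chars,
        fs=float(np.ravel(mat.get("fs", [240.0]))[0]),
    )


def write_competition_file(path: str, data: CompetitionData) -> None:
    """Write a recording in the competition MATLAB layout (for stand-ins)."""
    savemat(
        path,
        {
            "Signal": data.signal,
            "StimulusCode": data.stimulus_code,
            "StimulusType": data.stimulus_type,
            "TargetChar": data.target_chars,
            "fs": data.fs,
        },
    )


def synthetic_competition_data(
    n_letters: int = 8,
    n_sequences: int = 15,
    n_channels: int = 4,
    fs: float = 240.0,
    seed: int = 0,
) -> CompetitionData:
    """Synthetic stand-in recording in the competition layout.

    Generated by the pseudo-real simulator (template superposition on
    synthetic background) and re-packed per letter trial, so the optional
    competition runner can be exercised end to end without the external
    download.
    """
    timing = SpellerTiming(initial_pause=1.0, inter_trial_pause=2.0)
    session = simulate_session(
        n_trials=n_letters,
        n_sequences=n_sequences,
        n_channels=n_channels,
        fs=fs,
        timing=timing,
        seed=seed,
    )
    schedule = session.schedule
    flash_len = int(round(timing.flash_duration * fs))
    trial_len = int(round((12 * n_sequences * timing.soa + 1.0) * fs))

    signal = np.zeros((n_letters, trial_len, n_channels))
    code = np.zeros((n_letters, trial_len), dtype=int)
    stype = np.zeros((n_letters, trial_len), dtype=int)
    target_chars = []
    for t, trial in enumerate(schedule.trials):
        start = int(round(trial.events[0].onset * fs))
        signal[t] = session.data[:, start : start + trial_len].T
        for ev in trial.events:
            s = int(round(ev.onset * fs)) - start
            comp_code = ev.stimulus_id + 6 if ev.stimulus_id <= 6 else ev.stimulus_id - 6
            code[t, s : s + flash_len] = comp_code
            if ev.label:
                stype[t, s : s + flash_len] = 1
        target_chars.append(COMPETITION_LAYOUT[SPELLER_LAYOUT.index(trial.target)])
    return CompetitionData(
        signal=signal,
        stimulus_code=code,
        stimulus_type=stype,
        target_chars="".join(target_chars),
        fs=fs,
        channel_names=tuple(session.channel_names),
    )


def competition_to_session(data: CompetitionData) -> EEGStream:
    """Concatenate competition letter trials into one schedule-carrying stream.

    Competition stimulus codes (1-6 columns, 7-12 rows) are remapped to
    the package convention (1-6 rows, 7-12 columns), and target characters
    onto the package's 6x6 layout.  One second of padding separates
    trials so every final segment fits.
    """
    n_letters, trial_len, n_channels = data.signal.shape
    pad = int(round(data.fs))
    chunks, trials = [], []
    offset = 0
    for t in range(n_letters):
        chunk = np.concatenate([data.signal[t].T, np.zeros((n_channels, pad))], axis=1)
        chunks.append(chunk)
        code = data.stimulus_code[t]
        onsets = np.flatnonzero((code > 0) & (np.r_[0, code[:-1]] == 0))
        events = []
        for s in onsets:
            comp = int(code[s])
            sid = comp + 6 if comp <= 6 else comp - 6
            events.append(
                StimulusEvent(
                    onset=(offset + s) / data.fs,
                    stimulus_id=sid,
                    label=bool(data.stimulus_type[t, s]),
                    trial_index=t,
                )
            )
        trials.append(
            TrialSchedule(
                target=_competition_char_to_layout(data.target_chars[t]),
                events=tuple(events),
            )
        )
        offset += chunk.shape[1]
    n_sequences = len(trials[0].events) // 12 if trials else 0
    schedule = StimulusSchedule(
        trials=tuple(trials), timing=SpellerTiming(), n_sequences=n_sequences
    )
    return EEGStream(
        data=np.concatenate(chunks, axis=1),
        fs=data.fs,
        channel_names=data.channel_names,
        schedule=schedule,
    )


def run_competition_iib(
    data: CompetitionData | str,
    cfg: ExperimentConfig | None = None,
    split: tuple[int, int] = (42, 31),
) -> pd.DataFrame:
    """Offline speller simulation on a competition recording.

    Uses the first ``split[0]`` letters to build template dictionaries and
    the remaining ``split[1]`` for testing (clipped to what the file
    holds); reports letter accuracy per method and channel at the maximum
    available sequence count.
    """
    if isinstance(data, str):
        data = load_competition_iib(data)
    cfg = cfg or ExperimentConfig()
    session = competition_to_session(data)
    schedule = session.schedule
    n_train = min(split[0], max(1, schedule.n_trials - 1))
    n_test = min(split[1], schedule.n_trials - n_train)
    cfg = replace(
        cfg,
        split=(n_train, n_test),
        sequence_range=(schedule.n_sequences,),
        n_repeats=1,
    )
    processed = preprocess_session(session)
    segments = extract_segments(processed, schedule, reject_uv=cfg.reject_uv)
    cache = _FeatureCache(segments, schedule, processed.channel_names, cfg.methods, cfg)
    counts = _evaluate_split(
        cache, np.arange(n_train), np.arange(n_train, n_train + n_test), cfg
    )
    records = [
        {"method": m.value, "channel": chn, "n_sequences": n_seq, "accuracy": c / n_test}
        for (m, chn, n_seq), c in counts.items()
    ]
    return pd.DataFrame.from_records(records).sort_values(
        ["method", "channel"], ignore_index=True
    )
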