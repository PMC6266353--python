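"""Session container, feature tables, run configuration and logging.

A generated session is stored as a single hierarchical (HDF5) file whose
named datasets hold the EEG channels, an integer stimulus channel ``S``
(0 between flashes, 1-12 during a flash) and a label channel ``L`` (0
none, 1 non-target flash, 2 target flash — mirroring the single- versus
double-amplitude marker squares of a speller trace), plus the exact event
list and the metadata (rate, channel names, targets, seed and generation
config) needed to regenerate the session bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import (
    EEGStream,
    SpellerTiming,
    StimulusEvent,
    StimulusSchedule,
    TrialSchedule,
)

logger = logging.getLogger(__name__)

_EVENT_DTYPE = np.dtype(
    [("onset", "f8"), ("stimulus_id", "i4"), ("label", "i1"), ("trial_index", "i4")]
)


def configure_logging(level: int = logging.INFO) -> None:
    """Machine-readable logging: one ``key=value`` styled line per record."""
    logging.basicConfig(
        level=level,
        stream=sys.stderr,
        format="stage=%(name)s level=%(levelname)s msg=%(message)s",
        force=True,
    )


def marker_channels(stream: EEGStream) -> tuple[np.ndarray, np.ndarray]:
    """Build the integer stimulus channel S and label channel L."""
    schedule = stream.schedule
    if schedule is None:
        raise ValueError("stream carries no schedule")
    s = np.zeros(stream.n_samples, dtype=np.int8)
    label = np.zeros(stream.n_samples, dtype=np.int8)
    flash = int(round(schedule.timing.flash_duration * stream.fs))
    for ev in schedule.events:
        a = int(round(ev.onset * stream.fs))
        b = min(a + flash, stream.n_samples)
        s[a:b] = ev.stimulus_id
        label[a:b] = 2 if ev.label else 1
    return s, label


def write_session(path: str, stream: EEGStream, metadata: dict | None = None) -> None:
    """Write a session container (EEG + S + L + events + metadata)."""
    schedule = stream.schedule
    if schedule is None:
        raise ValueError("cannot write a session without a schedule")
    s, label = marker_channels(stream)
    events = np.array(
        [(ev.onset, ev.stimulus_id, int(ev.label), ev.trial_index) for ev in schedule.events],
        dtype=_EVENT_DTYPE,
    )
    meta = dict(metadata or {})
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=stream.data)
        f.create_dataset("S", data=s)
        f.create_dataset("L", data=label)
        f.create_dataset("events", data=events)
        f.attrs["fs"] = stream.fs
        f.attrs["channel_names"] = json.dumps(list(stream.channel_names))
        f.attrs["targets"] = json.dumps(list(schedule.targets))
        f.attrs["n_sequences"] = schedule.n_sequences
        f.attrs["timing"] = json.dumps(dataclasses.asdict(schedule.timing))
        f.attrs["metadata"] = json.dumps(meta)
    logger.info("wrote session path=%s channels=%d samples=%d events=%d",
                path, stream.n_channels, stream.n_samples, len(events))


def read_session(path: str) -> tuple[EEGStream, dict]:
    """Read a session container back; round-trips :func:`write_session`."""
    try:
        with h5py.File(path, "r") as f:
            required = {"eeg", "S", "L", "events"}
            present = set(f.keys())
            if not required <= present:
                raise ValueError(
                    f"session file {path} lacks datasets {sorted(required - present)}"
                )
            data = f["eeg"][()]
            events = f["events"][()]
            fs = float(f.attrs["fs"])
            channel_names = tuple(json.loads(f.attrs["channel_names"]))
            targets = json.loads(f.attrs["targets"])
            n_sequences = int(f.attrs["n_sequences"])
            timing = SpellerTiming(**json.loads(f.attrs["timing"]))
            metadata = json.loads(f.attrs["metadata"])
    except OSError as exc:
        raise ValueError(f"cannot open session file {path}: {exc}") from exc

    trials = []
    for t, target in enumerate(targets):
        trial_events = tuple(
            StimulusEvent(
                onset=float(e["onset"]),
                stimulus_id=int(e["stimulus_id"]),
                label=bool(e["label"]),
                trial_index=int(e["trial_index"]),
            )
            for e in events[events["trial_index"] == t]
        )
        trials.append(TrialSchedule(target=target, events=trial_events))
    schedule = StimulusSchedule(trials=tuple(trials), timing=timing, n_sequences=n_sequences)
    stream = EEGStream(data=data, fs=fs, channel_names=channel_names, schedule=schedule)
    return stream, metadata


def write_feature_table(path: str, table: pd.DataFrame, binary_mirror: bool = False) -> None:
    """Write a feature matrix as TSV (one row per averaged segment).

    With ``binary_mirror`` an ``.npz`` file holding the numeric block is
    written alongside for fast reloading.
    """
    table.to_csv(path, sep="\t", index=False)
    if binary_mirror:
        value_cols = [c for c in table.columns if c.startswith("v")]
        np.savez_compressed(path + ".npz", values=table[value_cols].to_numpy())
    logger.info("wrote feature table path=%s rows=%d", path, len(table))


def save_plot_image(path: str, image) -> None:
    """Export a rasterized signal plot as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    iio.imwrite(path, pixels[::-1].astype(np.uint8))  # row 0 at the bottom


@dataclasses.dataclass
class RunConfig:
    """Flat key-value document of every pipeline tunable.

    Unknown keys are rejected on load so configuration typos fail loudly.
    """

    # generation
    n_trials: int = 35
    n_sequences: int = 10
    n_channels: int = 8
    fs: float = 250.0
    experiment: int = 1
    modality: str = "active"
    latency_low: float = 0.0
    latency_high: float = 0.4
    gain_low: float = 0.0
    gain_high: float = 1.0
    pink_rms: float = 8.0
    alpha_amp: float = 10.0
    # preprocessing
    band_low: float = 0.1
    band_high: float = 10.0
    filter_order: int = 4
    notch_freq: float = 50.0
    target_fs: float = 16.0
    reject_uv: float = 70.0
    # features
    mp_atoms: int = 5
    pe_m: int = 3
    pe_tau: int = 1
    pe_window: int = 8
    shcc_g: int = 32
    sift_delta: int = 4
    sift_sigma: float = 1.0
    sift_clamp: float = 0.2
    # classification / benchmarking
    k: int = 3
    split_train: int = 15
    split_test: int = 20
    n_repeats: int = 100
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=False)

    def filter_spec(self):
        from .preprocess import FilterSpec

        return FilterSpec(
            band_low=self.band_low,
            band_high=self.band_high,
            order=self.filter_order,
            notch_freq=self.notch_freq,
            target_fs=self.target_fs,
        )

    def feature_cfg(self):
        from .features import FeatureConfig, PEConfig, SHCCConfig, SIFTConfig

        return FeatureConfig(
            mp_atoms=self.mp_atoms,
            pe=PEConfig(W=self.pe_window, m=self.pe_m, tau=self.pe_tau),
            shcc=SHCCConfig(G=self.shcc_g),
            sift=SIFTConfig(smooth_sigma=self.sift_sigma, clamp=self.sift_clamp),
            delta=self.sift_delta,
        )

    def noise_cfg(self):
        from .synth import NoiseConfig

        return NoiseConfig(
            latency_low=self.latency_low,
            latency_high=self.latency_high,
            gain_low=self.gain_low,
            gain_high=self.gain_high,
        )

    def experiment_cfg(self, **overrides):
        from .bench import ExperimentConfig

        kwargs = dict(
            experiment=self.experiment,
            modality=self.modality,
            n_repeats=self.n_repeats,
            split=(self.split_train, self.split_test),
            k=self.k,
            mp_atoms=self.mp_atoms,
            reject_uv=self.reject_uv,
            feature_cfg=self.feature_cfg(),
            noise=self.noise_cfg(),
            seed=self.seed,
            n_trials=self.n_trials,
            n_sequences=self.n_sequences,
            n_channels=self.n_channels,
            fs=self.fs,
            pink_rms=self.pink_rms,
            alpha_amp=self.alpha_amp,
            sequence_range=tuple(range(1, self.n_sequences + 1)),
        )
        kwargs.update(overrides)
        return ExperimentConfig(**kwargs)
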