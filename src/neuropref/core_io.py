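"""Domain types, file readers/writers, and run configuration.

The interchange formats are deliberately plain: EEG trial matrices are
delimited text (channels x samples, whitespace or comma separated), label
tables are CSV/TSV with a header, and feature tables round-trip through
pandas at full float precision.  All downstream stages consume the types
defined here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_CHANNELS",
    "FRONTAL_CHANNELS",
    "ChannelMontage",
    "EEGRecording",
    "TrialEpoch",
    "LabelTable",
    "RunConfig",
    "canonical_montage",
    "read_eeg_matrix",
    "write_eeg_matrix",
    "read_label_table",
    "write_label_table",
    "write_feature_table",
    "read_feature_table",
    "load_config",
    "ParseError",
    "ShapeError",
    "SchemaError",
    "ValidationError",
]

#: Emotiv EPOC+ 10-20 subset, in canonical listing order.
CANONICAL_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Frontal electrodes entering the preference-index calculation.
FRONTAL_CHANNELS = ("AF3", "F3", "AF4", "F4")

_LEFT = {"AF3", "F7", "F3", "FC5", "T7", "P7", "O1"}
_RIGHT = {"AF4", "F8", "F4", "FC6", "T8", "P8", "O2"}


class ParseError(ValueError):
    """Malformed numeric content in a delimited matrix file."""


class ShapeError(ValueError):
    """Matrix dimensions incompatible with the montage."""


class SchemaError(ValueError):
    """Inconsistent feature names or table columns."""


class ValidationError(ValueError):
    """Configuration value outside its legal range, or unknown key."""


def _hemisphere(label: str) -> str:
    if label in _LEFT:
        return "left"
    if label in _RIGHT:
        return "right"
    return "midline"


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered electrode labels with a left/right/midline hemisphere map."""

    labels: tuple[str, ...]
    hemisphere: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise ValidationError("montage labels must be unique")
        object.__setattr__(self, "labels", labels)
        if not self.hemisphere:
            object.__setattr__(
                self, "hemisphere", {lab: _hemisphere(lab) for lab in labels}
            )

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage {self.labels}") from None

    def subset(self, labels: Sequence[str]) -> "ChannelMontage":
        for lab in labels:
            self.index(lab)
        return ChannelMontage(tuple(labels))


def canonical_montage() -> ChannelMontage:
    """The 14-channel Emotiv EPOC+ montage in canonical order."""
    return ChannelMontage(CANONICAL_CHANNELS)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    montage: ChannelMontage
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("EEG data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.montage):
            raise ShapeError(
                f"{self.data.shape[0]} rows but montage has {len(self.montage)} labels"
            )
        if not self.rate > 0:
            raise ValidationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("EEG data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, **kw) -> "EEGRecording":
        params = dict(
            data=self.data, rate=self.rate, montage=self.montage,
            subject_id=self.subject_id,
        )
        params.update(kw)
        return EEGRecording(**params)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.montage.index(label)]


@dataclass
class TrialEpoch:
    """One stimulus-locked fixed-length EEG segment (canonically 4 s)."""

    recording: EEGRecording
    stimulus_id: str
    subjective_label: str = "unknown"

    def __post_init__(self):
        if self.subjective_label not in ("like", "dislike", "unknown"):
            raise ValidationError(
                f"subjective_label must be like/dislike/unknown, got {self.subjective_label!r}"
            )

    @property
    def duration(self) -> float:
        return self.recording.duration

    @property
    def subject_id(self) -> str:
        return self.recording.subject_id


class LabelTable:
    """Per-trial subjective responses keyed by (subject_id, stimulus_id)."""

    REQUIRED = ("subject_id", "stimulus_id", "subjective_label")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise SchemaError(f"label table missing columns {missing}")
        frame = frame.copy()
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["stimulus_id"] = frame["stimulus_id"].astype(str)
        frame["subjective_label"] = frame["subjective_label"].astype(str).str.lower()
        bad = set(frame["subjective_label"]) - {"like", "dislike"}
        if bad:
            raise ValidationError(f"unrecognized labels {sorted(bad)}")
        keys = list(zip(frame["subject_id"], frame["stimulus_id"]))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (subject, stimulus) keys: {dupes[:5]}")
        if "nine_point_rank" in frame.columns:
            ranks = frame["nine_point_rank"].dropna()
            if len(ranks) and not ranks.between(1, 9).all():
                raise ValidationError("nine_point_rank values must lie in [1, 9]")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def label_of(self, subject_id: str, stimulus_id: str) -> str:
        sel = self.frame[
            (self.frame["subject_id"] == str(subject_id))
            & (self.frame["stimulus_id"] == str(stimulus_id))
        ]
        if sel.empty:
            raise KeyError((subject_id, stimulus_id))
        return sel["subjective_label"].iloc[0]

    @property
    def labels(self) -> np.ndarray:
        return self.frame["subjective_label"].to_numpy()


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class PreprocessParams:
    target_rate: float = 128.0
    band: tuple[float, float] = (4.0, 45.0)
    sg_window: int = 11
    sg_order: int = 3
    ica_enabled: bool = True
    kurtosis_threshold: float = 5.0
    car_enabled: bool = True

    def validate(self):
        if self.sg_window % 2 == 0:
            raise ValidationError("sg_window must be odd")
        if self.sg_window <= self.sg_order:
            raise ValidationError("sg_window must exceed sg_order")
        low, high = self.band
        if not (0 < low < high):
            raise ValidationError("band edges must satisfy 0 < low < high")
        if high >= self.target_rate / 2:
            raise ValidationError("band high edge must be below Nyquist")


@dataclass
class FeatureParams:
    wavelet: str = "db4"
    levels: int = 4
    welch_segment: int = 256
    welch_overlap: float = 0.5
    welch_window: str = "hann"
    bands: dict = field(default_factory=lambda: {
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 40.0),
    })

    def validate(self):
        if self.levels < 1:
            raise ValidationError("levels must be >= 1")
        if not 0 <= self.welch_overlap < 1:
            raise ValidationError("welch_overlap must lie in [0, 1)")
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi):
                raise ValidationError(f"band {name!r} edges out of order")


@dataclass
class ClassifierParams:
    rf_trees: int = 500
    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_cost: float = 1.0
    dnn_learning_rate: float = 0.001
    dnn_dropout: float = 0.5
    dnn_epochs: int = 80
    dnn_batch_size: int = 32
    dnn_patience: int = 10
    dnn_start_epoch: int = 30
    dnn_regularization: str = "none"  # l1 | l2 | gaussian_noise | none

    def validate(self):
        if self.rf_trees < 1:
            raise ValidationError("rf_trees must be >= 1")
        if not self.dnn_learning_rate > 0:
            raise ValidationError("learning rate must be positive")
        if not 0 <= self.dnn_dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")


@dataclass
class RunConfig:
    """Parameters for the full pipeline; defaults follow the study setup."""

    preprocessing: PreprocessParams = field(default_factory=PreprocessParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    classifiers: ClassifierParams = field(default_factory=ClassifierParams)
    split_fraction: float = 0.2
    seed: int = 0

    def validate(self):
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split_fraction must lie in (0, 1)")
        self.preprocessing.validate()
        self.features.validate()
        self.classifiers.validate()
        return self


def _update_dataclass(obj, values: Mapping, path: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in names:
            raise ValidationError(f"unknown config key {path}{key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, Mapping):
            _update_dataclass(current, val, f"{path}{key}.")
        elif key == "band" or (key == "bands" and isinstance(val, Mapping)):
            if key == "band":
                setattr(obj, key, tuple(float(v) for v in val))
            else:
                setattr(obj, key, {k: tuple(map(float, v)) for k, v in val.items()})
        else:
            setattr(obj, key, type(current)(val) if current is not None else val)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; absent keys take the study defaults.

    An empty or missing file yields the full default configuration
    (4-45 Hz band, 128 Hz, db4 level 4, RF 500 trees, dropout 0.5,
    learning rate 0.001, 20% holdout).  Unknown keys raise
    :class:`ValidationError`.
    """
    cfg = RunConfig()
    if path is not None:
        text = Path(path).read_text()
        values = yaml.safe_load(text) or {}
        if not isinstance(values, Mapping):
            raise ValidationError("config root must be a mapping")
        _update_dataclass(cfg, values, "")
    return cfg.validate()


# ---------------------------------------------------------------------------
# Delimited-matrix EEG reader/writer

def _sniff_delimiter(sample_line: str) -> str | None:
    return "," if "," in sample_line else None  # None -> any whitespace


def read_eeg_matrix(
    path: str | Path,
    rate: float,
    montage: ChannelMontage | None = None,
    subject_id: str = "",
) -> EEGRecording:
    """Read a delimited numeric matrix as an EEG recording.

    Orientation is auto-detected: whichever dimension equals the montage
    size is taken as channels.  Square matrices are assumed channels-first.
    """
    montage = montage or canonical_montage()
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = []
    for i, ln in enumerate(lines, start=1):
        parts = ln.split(delim) if delim else ln.split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from None
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    mat = np.asarray(rows, dtype=float)
    n = len(montage)
    if mat.shape[0] == n:
        pass
    elif mat.shape[1] == n:
        mat = mat.T
    else:
        raise ShapeError(
            f"{path}: neither dimension of {mat.shape} matches montage size {n}"
        )
    return EEGRecording(mat, rate=rate, montage=montage, subject_id=subject_id)


def write_eeg_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write the channels x samples matrix as tab-delimited text."""
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")


def read_label_table(path: str | Path) -> LabelTable:
    """Read a CSV/TSV label table with a header row."""
    frame = pd.read_csv(path, sep=None, engine="python")
    return LabelTable(frame)


def write_label_table(table: LabelTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def write_feature_table(features: Sequence[Mapping[str, float]],
                        path: str | Path,
                        keys: Sequence[Mapping[str, str]] | None = None) -> None:
    """Write per-trial named feature vectors as a CSV table.

    Every vector must carry the identical ordered feature-name set; the
    column order of the first vector is preserved.  ``keys`` optionally
    prepends identifier columns (subject_id, stimulus_id, label).
    """
    features = list(features)
    if features:
        names = list(features[0])
        for i, vec in enumerate(features):
            if list(vec) != names:
                raise SchemaError(f"trial {i} feature names differ from trial 0")
    else:
        names = []
    frame = pd.DataFrame([dict(v) for v in features], columns=names)
    if keys is not None:
        kf = pd.DataFrame(list(keys))
        frame = pd.concat([kf, frame], axis=1)
    # pandas' default float formatting is shortest-repr, hence lossless
    frame.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so written floats are recovered bit-exactly
    return pd.read_csv(path, float_precision="round_trip")
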