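"""Synthetic 14-channel EEG with a planted like/dislike band-power asymmetry.

Each trial is a sum of band-limited oscillations (theta, alpha, beta, gamma)
plus Gaussian broadband noise.  A latent binary preference state modulates
the left/right frontal contrast: a "like" trial raises beta and lowers alpha
on the left frontal electrodes (AF3, F3) relative to the right (AF4, F4),
consistent with left-frontal activation indexing positive valence; "dislike"
mirrors the contrast.  Non-frontal channels are unaffected by the label, so
the planted effect is exactly where the preference indices look.

The generator emulates the shape of the neuromarketing acquisition it stands
in for: 25 subjects x 42 product stimuli (14 products x 3 variants), 14
channels at 128 Hz, 4 s per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    ChannelMontage,
    EEGRecording,
    LabelTable,
    TrialEpoch,
    ValidationError,
    canonical_montage,
)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "make_band_oscillation",
    "synth_trial",
    "synth_dataset",
    "DEFAULT_BANDS",
    "DEFAULT_AMPLITUDES",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

#: Baseline per-band oscillation amplitudes (microvolts, RMS).  Alpha
#: dominates, with progressively weaker beta and gamma, a coarse but
#: standard caricature of resting scalp EEG.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "theta": 4.0,
    "alpha": 6.0,
    "beta": 3.0,
    "gamma": 1.5,
}

_LEFT_FRONTAL = ("AF3", "F3")
_RIGHT_FRONTAL = ("AF4", "F4")


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the emulated acquisition."""

    n_subjects: int = 25
    trials_per_subject: int = 42
    n_products: int = 14
    variants_per_product: int = 3
    rate: float = 128.0
    duration: float = 4.0
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    asymmetry_effect: float = 1.0
    noise_sd: float = 2.0
    like_fraction: float = 0.5
    label_flip_prob: float = 0.0
    artifact_prob: float = 0.0  # optional sinusoid+spike contaminant
    seed: int = 0

    def validate(self):
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if not 0 <= self.like_fraction <= 1:
            raise ValidationError("like_fraction must lie in [0, 1]")
        if self.asymmetry_effect < 0:
            raise ValidationError("asymmetry_effect must be >= 0")
        nyq = self.rate / 2
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi < nyq):
                raise ValidationError(
                    f"band {name!r} ({lo}, {hi}) must lie within (0, {nyq})")
        return self


@dataclass
class SynthTruth:
    """Ground truth for one generated dataset."""

    frame: pd.DataFrame  # subject_id, stimulus_id, latent_label,
    #                      alpha_left, alpha_right (planted amplitudes)

    def __len__(self):
        return len(self.frame)

    @property
    def latent_labels(self) -> np.ndarray:
        return self.frame["latent_label"].to_numpy()


def make_band_oscillation(
    band: tuple[float, float],
    amplitude: float,
    duration: float,
    rate: float,
    rng: np.random.Generator,
    n_components: int = 8,
) -> np.ndarray:
    """Zero-mean random-phase sinusoid mixture confined to ``band``.

    The mixture of ``n_components`` equal-weight sinusoids at frequencies
    drawn uniformly in [low, high] is scaled to RMS ``amplitude``, so its
    Welch power concentrates inside the band.
    """
    low, high = band
    if not (0 < low < high):
        raise ValidationError(f"band edges ({low}, {high}) out of order")
    if high >= rate / 2:
        raise ValidationError(
            f"band high edge {high} Hz at or above Nyquist {rate / 2} Hz")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if amplitude == 0:
        return np.zeros(n)
    freqs = rng.uniform(low, high, size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    sig = np.sum(np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
                 axis=0)
    rms = np.sqrt(np.mean(sig**2))
    if rms > 0:
        sig = sig * (amplitude / rms)
    return sig - sig.mean()


def _band_gain(band_name: str, side: str, label: str, d: float) -> float:
    """Amplitude modulation for frontal channels.

    ``d`` scales the left-right contrast: the favoured direction is
    multiplied by (1 + d/4) and the opposite by (1 - d/4), floored at 0.05.
    For a "like" trial the left beta and right alpha rise; "dislike"
    mirrors the pattern.  Theta and gamma are untouched.
    """
    if band_name not in ("alpha", "beta") or d == 0:
        return 1.0
    r = d / 4.0
    sign = 1.0 if label == "like" else -1.0
    if band_name == "alpha":
        delta = r if side == "right" else -r
    else:  # beta
        delta = r if side == "left" else -r
    return max(1.0 + sign * delta, 0.05)


def synth_trial(
    config: SynthConfig,
    label: str,
    rng: np.random.Generator,
    stimulus_id: str = "s00",
    subject_id: str = "sub00",
    montage: ChannelMontage | None = None,
) -> tuple[TrialEpoch, dict]:
    """Generate one labelled trial; returns the epoch and its planted truth."""
    config.validate()
    if label not in ("like", "dislike"):
        raise ValidationError(f"label must be like/dislike, got {label!r}")
    montage = montage or canonical_montage()
    n = int(round(config.duration * config.rate))
    data = np.empty((len(montage), n))
    planted = {}
    for ci, ch in enumerate(montage.labels):
        if ch in _LEFT_FRONTAL:
            side = "left"
        elif ch in _RIGHT_FRONTAL:
            side = "right"
        else:
            side = "other"
        sig = np.zeros(n)
        for band_name, edges in config.bands.items():
            amp = config.amplitudes.get(band_name, 0.0)
            if side in ("left", "right"):
                amp *= _band_gain(band_name, side, label, config.asymmetry_effect)
            if band_name == "alpha" and ch in ("F3", "F4"):
                planted[f"alpha_{side}"] = amp
            sig += make_band_oscillation(
                edges, amp, config.duration, config.rate, rng)
        sig += rng.normal(0.0, config.noise_sd, size=n)
        if config.artifact_prob > 0 and rng.random() < config.artifact_prob:
            # single-channel contaminant: slow sinusoid plus one spike
            t = np.arange(n) / config.rate
            sig += 30.0 * np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 2 * np.pi))
            sig[rng.integers(n)] += 120.0
        data[ci] = sig
    rec = EEGRecording(data, rate=config.rate, montage=montage,
                       subject_id=subject_id)
    epoch = TrialEpoch(rec, stimulus_id=stimulus_id, subjective_label=label)
    return epoch, planted


def synth_dataset(
    config: SynthConfig,
) -> tuple[list[TrialEpoch], LabelTable, SynthTruth]:
    """Generate the full dataset: epochs, subjective label table, and truth.

    Latent labels are i.i.d. Bernoulli(``like_fraction``); the subjective
    label equals the latent label except with probability
    ``label_flip_prob`` per trial.  Stimulus ids enumerate products and
    variants (``p01_v1`` ... ``p14_v3`` at defaults).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    montage = canonical_montage()
    stimuli = [
        f"p{p + 1:02d}_v{v + 1}"
        for p in range(config.n_products)
        for v in range(config.variants_per_product)
    ][: config.trials_per_subject]
    if len(stimuli) < config.trials_per_subject:
        stimuli += [f"x{i}" for i in range(config.trials_per_subject - len(stimuli))]

    epochs: list[TrialEpoch] = []
    truth_rows = []
    label_rows = []
    for s in range(config.n_subjects):
        subject_id = f"sub{s + 1:02d}"
        for stim in stimuli:
            latent = "like" if rng.random() < config.like_fraction else "dislike"
            subjective = latent
            if config.label_flip_prob > 0 and rng.random() < config.label_flip_prob:
                subjective = "dislike" if latent == "like" else "like"
            epoch, planted = synth_trial(
                config, latent, rng, stimulus_id=stim,
                subject_id=subject_id, montage=montage)
            epoch.subjective_label = subjective
            epochs.append(epoch)
            truth_rows.append({
                "subject_id": subject_id,
                "stimulus_id": stim,
                "latent_label": latent,
                "alpha_left": planted.get("alpha_left", np.nan),
                "alpha_right": planted.get("alpha_right", np.nan),
            })
            label_rows.append({
                "subject_id": subject_id,
                "stimulus_id": stim,
                "subjective_label": subjective,
            })
    truth = SynthTruth(pd.DataFrame(truth_rows))
    labels = LabelTable(pd.DataFrame(label_rows))
    return epochs, labels, truth
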