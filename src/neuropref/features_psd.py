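"""Welch power spectral density and band-power features.

Band powers are the *mean* spectral density within half-open frequency
intervals [low, high): theta 4-8, alpha 8-13, beta 13-30, gamma 30-40 Hz.
Default Welch settings: 256-sample (2 s at 128 Hz) Hann segments with 50%
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import FeatureParams, ShapeError, TrialEpoch, ValidationError

__all__ = [
    "PowerSpectrum",
    "BandPowerSet",
    "welch_psd",
    "band_power",
    "band_powers",
    "psd_features_trial",
]


@dataclass
class PowerSpectrum:
    """One-sided Welch spectrum: density in microvolt^2/Hz on a Hz grid."""

    frequencies: np.ndarray
    power: np.ndarray
    channel: str = ""

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ShapeError("frequency and power grids differ in length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("spectral power must be non-negative")


@dataclass
class BandPowerSet:
    """Per-channel mean in-band power for a fixed set of named bands."""

    powers: dict[str, dict[str, float]]  # channel -> band name -> power
    bands: dict[str, tuple[float, float]]

    def get(self, channel: str, band: str) -> float:
        return self.powers[channel][band]


def welch_psd(x: np.ndarray, rate: float,
              segment: int = 256, overlap: float = 0.5,
              window: str = "hann", channel: str = "") -> PowerSpectrum:
    """Averaged modified periodogram over overlapping windowed segments."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError("welch_psd expects a 1-D signal")
    if segment > len(x):
        raise ValidationError(
            f"segment length {segment} exceeds signal length {len(x)}")
    noverlap = int(segment * overlap)
    f, p = sps.welch(x, fs=rate, window=window, nperseg=segment,
                     noverlap=noverlap)
    return PowerSpectrum(f, p, channel=channel)


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Mean spectral density over the half-open interval [low, high)."""
    low, high = band
    mask = (spectrum.frequencies >= low) & (spectrum.frequencies < high)
    if not mask.any():
        raise ValidationError(
            f"no spectral bins inside band ({low}, {high}) Hz")
    return float(spectrum.power[mask].mean())


def band_powers(epoch: TrialEpoch,
                params: FeatureParams | None = None,
                channels: list[str] | None = None) -> BandPowerSet:
    """Welch band powers for every (channel, band) pair of an epoch."""
    params = params or FeatureParams()
    rec = epoch.recording
    channels = list(channels) if channels is not None else list(rec.montage.labels)
    powers: dict[str, dict[str, float]] = {}
    for ch in channels:
        spec = welch_psd(rec.channel(ch), rec.rate,
                         segment=min(params.welch_segment, rec.n_samples),
                         overlap=params.welch_overlap,
                         window=params.welch_window, channel=ch)
        powers[ch] = {name: band_power(spec, edges)
                      for name, edges in params.bands.items()}
    return BandPowerSet(powers, dict(params.bands))


def psd_features_trial(epoch: TrialEpoch,
                       params: FeatureParams | None = None) -> dict[str, float]:
    """Named band-power feature vector: one entry per channel x band.

    Names like ``AF4.alpha``; length 4 x channels (56 at the canonical
    montage).
    """
    params = params or FeatureParams()
    bp = band_powers(epoch, params)
    features: dict[str, float] = {}
    for ch in epoch.recording.montage.labels:
        for band in params.bands:
            features[f"{ch}.{band}"] = bp.get(ch, band)
    return features
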