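"""Level-4 db4 wavelet decomposition and the 12-statistic feature scheme.

Each channel is decomposed by a cascaded two-channel filter bank into one
approximation (A4) and four detail (D4..D1) coefficient series.  At 128 Hz
a detail at level L spans the dyadic band (fs/2^(L+1), fs/2^L):

    D1 32-64 Hz (gamma), D2 16-32 (beta), D3 8-16 (alpha),
    D4 4-8 (theta), A4 0-4 (delta).

Twelve scalars summarize every coefficient series: mean, median, variance,
standard deviation, 25th/75th percentiles, RMS, zero- and mean-crossing
rates, mean first difference, Shannon entropy of the normalized
coefficient-energy distribution, and total energy.  Over 5 coefficient sets
and 14 channels this yields the canonical 12 x 5 x 14 = 840 features.

The transform uses periodized boundary handling so that the orthogonal db4
filter bank conserves energy exactly and reconstructs perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core_io import FeatureParams, ShapeError, TrialEpoch, ValidationError

__all__ = [
    "WaveletDecomposition",
    "FEATURE_NAMES",
    "dwt_decompose",
    "dwt_reconstruct",
    "band_of_level",
    "coeff_feature_vector",
    "dwt_features_trial",
]

#: Ordered names of the 12 per-coefficient statistics.
FEATURE_NAMES = (
    "mean", "median", "variance", "std", "p25", "p75",
    "rms", "zcr", "mcr", "mean_diff", "entropy", "energy",
)

_BAND_NAMES = {1: "gamma", 2: "beta", 3: "alpha", 4: "theta"}

_DWT_MODE = "periodization"


def band_of_level(level: int, fs: float, levels: int = 4,
                  approximation: bool = False) -> tuple[float, float]:
    """Nominal frequency band of a decomposition coefficient.

    Detail at level L spans (fs/2^(L+1), fs/2^L); the approximation at the
    deepest level spans (0, fs/2^(levels+1)).
    """
    if fs <= 0:
        raise ValidationError("fs must be positive")
    if approximation:
        return (0.0, fs / 2 ** (levels + 1))
    if not 1 <= level <= levels:
        raise ValidationError(f"detail level {level} outside [1, {levels}]")
    return (fs / 2 ** (level + 1), fs / 2 ** level)


@dataclass
class WaveletDecomposition:
    """Coefficient series A{L}, D{L}..D1 with nominal band annotations."""

    coefficients: dict[str, np.ndarray]
    bands: dict[str, tuple[float, float]]
    band_names: dict[str, str]
    wavelet: str
    levels: int

    def __post_init__(self):
        if len(self.coefficients) != self.levels + 1:
            raise ValidationError(
                f"expected {self.levels + 1} coefficient series, "
                f"got {len(self.coefficients)}")

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)


def dwt_decompose(x: np.ndarray, wavelet: str = "db4", levels: int = 4,
                  fs: float = 128.0) -> WaveletDecomposition:
    """Cascaded filter-bank decomposition with dyadic down-sampling."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError("dwt_decompose expects a 1-D signal")
    w = pywt.Wavelet(wavelet)
    max_lev = pywt.dwt_max_level(len(x), w.dec_len)
    if levels > max_lev:
        raise ValidationError(
            f"signal of length {len(x)} supports at most {max_lev} "
            f"levels with {wavelet}")
    arrs = pywt.wavedec(x, w, level=levels, mode=_DWT_MODE)
    names = [f"A{levels}"] + [f"D{lv}" for lv in range(levels, 0, -1)]
    coefficients = dict(zip(names, arrs))
    bands, band_names = {}, {}
    for name in names:
        if name.startswith("A"):
            bands[name] = band_of_level(0, fs, levels, approximation=True)
            band_names[name] = "delta" if levels == 4 and fs == 128 else "approx"
        else:
            lv = int(name[1:])
            bands[name] = band_of_level(lv, fs, levels)
            band_names[name] = _BAND_NAMES.get(lv, name) if fs == 128 else name
    return WaveletDecomposition(coefficients, bands, band_names, wavelet, levels)


def dwt_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse transform from all coefficient series."""
    names = [f"A{dec.levels}"] + [f"D{lv}" for lv in range(dec.levels, 0, -1)]
    arrs = [dec.coefficients[n] for n in names]
    return pywt.waverec(arrs, pywt.Wavelet(dec.wavelet), mode=_DWT_MODE)


def _crossing_rate(x: np.ndarray) -> float:
    # sign(0) treated as positive so exact zeros do not double-count
    s = np.where(x >= 0, 1, -1)
    return float(np.count_nonzero(s[1:] != s[:-1]) / (len(x) - 1)) if len(x) > 1 else 0.0


def _shannon_entropy(x: np.ndarray) -> float:
    e = x.astype(float) ** 2
    total = e.sum()
    if total == 0:
        return 0.0
    p = e / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def coeff_feature_vector(coeff: np.ndarray) -> dict[str, float]:
    """The ordered 12-statistic summary of one coefficient series.

    Crossing rates are fractions of adjacent sample pairs; entropy is
    computed on the normalized squared-coefficient distribution with
    natural log (0 log 0 := 0); energy is the sum of squared coefficients.
    """
    x = np.asarray(coeff, dtype=float)
    if x.size == 0:
        raise ValidationError("empty coefficient vector")
    diffs = np.diff(x)
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "variance": float(x.var()),
        "std": float(x.std()),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "zcr": _crossing_rate(x),
        "mcr": _crossing_rate(x - x.mean()),
        "mean_diff": float(diffs.mean()) if diffs.size else 0.0,
        "entropy": _shannon_entropy(x),
        "energy": float(np.sum(x**2)),
    }


def dwt_features_trial(epoch: TrialEpoch,
                       params: FeatureParams | None = None) -> dict[str, float]:
    """Named DWT feature vector for one epoch.

    Concatenates channels x coefficients x 12 statistics with names like
    ``F3.D3.rms``; length 12 x (levels+1) x channels (840 at the canonical
    14-channel montage and 4 levels).
    """
    params = params or FeatureParams()
    rec = epoch.recording
    features: dict[str, float] = {}
    for ch in rec.montage.labels:
        dec = dwt_decompose(rec.channel(ch), params.wavelet, params.levels,
                            fs=rec.rate)
        for cname, coeff in dec.coefficients.items():
            stats = coeff_feature_vector(coeff)
            for fname, val in stats.items():
                features[f"{ch}.{cname}.{fname}"] = val
    return features
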