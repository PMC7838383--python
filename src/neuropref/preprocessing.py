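"""Signal conditioning: re-referencing, resampling, band-pass filtering,
artifact removal (ICA + Savitzky-Golay), epoching and channel selection.

The canonical chain is reference -> resample -> bandpass -> artifact
removal, applied by :func:`preprocess`.  All stages preserve channel count
and montage; only resampling changes the sample count.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA

from .core_io import (
    EEGRecording,
    PreprocessParams,
    TrialEpoch,
    ValidationError,
)

__all__ = [
    "PreprocessParams",
    "common_average_reference",
    "resample_to_target",
    "bandpass_filter",
    "remove_artifacts",
    "epoch_trial",
    "select_channels",
    "preprocess",
]


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValidationError("common average reference needs >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def resample_to_target(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Polyphase resampling to ``target_rate`` (anti-aliased on decimation)."""
    if target_rate <= 0:
        raise ValidationError("target_rate must be positive")
    if target_rate == rec.rate:
        return rec.copy_with()
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=data, rate=target_rate)


def bandpass_filter(rec: EEGRecording, band: tuple[float, float],
                    order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    low, high = band
    nyq = rec.rate / 2
    if not (0 < low < high):
        raise ValidationError(f"band edges ({low}, {high}) out of order")
    if high >= nyq:
        raise ValidationError(f"band high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate,
                     output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def _reject_components_ica(data: np.ndarray, threshold: float,
                           seed: int) -> np.ndarray:
    """FastICA unmixing; zero out components with extreme excess kurtosis.

    High-kurtosis components capture spiky, transient activity (blinks,
    electrode pops) rather than ongoing oscillations.
    """
    n_ch = data.shape[0]
    ica = FastICA(n_components=n_ch, whiten="unit-variance",
                  random_state=seed, max_iter=500, tol=1e-3)
    sources = ica.fit_transform(data.T)  # samples x components
    k = kurtosis(sources, axis=0, fisher=True)
    keep = np.abs(k) <= threshold
    if keep.all():
        return data
    sources[:, ~keep] = 0.0
    cleaned = ica.inverse_transform(sources).T
    return cleaned


def remove_artifacts(rec: EEGRecording, params: PreprocessParams,
                     seed: int = 0) -> EEGRecording:
    """ICA-based component rejection followed by Savitzky-Golay smoothing.

    With ``ica_enabled`` false the stage reduces to per-channel smoothing.
    Output shape equals input shape.
    """
    params.validate()
    data = rec.data
    if params.ica_enabled:
        if rec.n_samples < 5 * rec.n_channels:
            raise ValidationError(
                "too few samples for ICA (need >= 5 x channels)")
        data = _reject_components_ica(data, params.kurtosis_threshold, seed)
    data = sps.savgol_filter(data, window_length=params.sg_window,
                             polyorder=params.sg_order, axis=1)
    return rec.copy_with(data=data)


def epoch_trial(rec: EEGRecording, onset: float, duration: float,
                stimulus_id: str, label: str = "unknown") -> TrialEpoch:
    """Half-open slice [onset, onset + duration) as a stimulus-locked epoch."""
    start = int(round(onset * rec.rate))
    stop = start + int(round(duration * rec.rate))
    if start < 0 or stop > rec.n_samples:
        raise IndexError(
            f"epoch [{onset}, {onset + duration}) s outside recording of "
            f"{rec.duration} s")
    seg = rec.copy_with(data=rec.data[:, start:stop])
    return TrialEpoch(seg, stimulus_id=stimulus_id, subjective_label=label)


def select_channels(rec: EEGRecording, labels: list[str]) -> EEGRecording:
    """Restrict to the requested channels, in the requested order."""
    idx = [rec.montage.index(lab) for lab in labels]
    return EEGRecording(rec.data[idx], rate=rec.rate,
                        montage=rec.montage.subset(labels),
                        subject_id=rec.subject_id)


def preprocess(rec: EEGRecording, params: PreprocessParams | None = None,
               seed: int = 0) -> EEGRecording:
    """Full conditioning chain: CAR -> resample -> bandpass -> artifacts."""
    params = params or PreprocessParams()
    params.validate()
    out = rec
    if params.car_enabled:
        out = common_average_reference(out)
    out = resample_to_target(out, params.target_rate)
    out = bandpass_filter(out, params.band)
    out = remove_artifacts(out, params, seed=seed)
    return out
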