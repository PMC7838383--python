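"""EEG preference indices from frontal band-power asymmetry.

Four index families are computed from Welch band powers at the frontal
electrodes AF3, F3 (left) and AF4, F4 (right):

* approach-withdrawal:  AW = (alpha(F4) - alpha(F3)) / (alpha(F4) + alpha(F3))
* effort:               (theta(F4) - theta(F3)) / (theta(F4) + theta(F3))
* choice (per band b in {beta, gamma}, at AF3/AF4):
                        (ln b(AF3) - ln b(AF4)) / (ln b(AF3) + ln b(AF4))
* valence, four variants:
    v1 = beta(AF3,F3)/alpha(AF3,F3) - beta(AF4,F4)/alpha(AF4,F4)
    v2 = ln alpha(AF3,F3) - ln alpha(AF4,F4)
    v3 = alpha(F4) - beta(F3)
    v4 = alpha(F4)/beta(F4) - alpha(F3)/beta(F3)

Pair powers like alpha(AF3,F3) are the arithmetic mean of the two channel
powers.  Greater right-hemisphere alpha (left-frontal activation) is read
as positive valence, i.e. approach / "like".

A continuous valence variant is turned into like/dislike labels by
rescaling it per subject onto a 1-9 rank scale and thresholding: ranks 1-5
are "dislike", 6-9 "like".  Agreement between subjective and valence-based
labels is quantified by Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import FeatureParams, TrialEpoch, ValidationError
from .features_psd import BandPowerSet, band_powers

__all__ = [
    "PreferenceIndices",
    "INDEX_NAMES",
    "aw_index",
    "effort_index",
    "choice_index",
    "valence_indices",
    "all_indices_trial",
    "index_table",
    "valence_to_ninepoint",
    "ninepoint_to_label",
    "valence_labels",
    "cohens_kappa",
    "DegenerateInputError",
]

INDEX_NAMES = (
    "aw", "effort", "choice_beta", "choice_gamma",
    "valence_v1", "valence_v2", "valence_v3", "valence_v4",
)

_LEFT_PAIR = ("AF3", "F3")
_RIGHT_PAIR = ("AF4", "F4")


class DegenerateInputError(ValueError):
    """Band powers admit no well-defined index (zero denominator etc.)."""


@dataclass(frozen=True)
class PreferenceIndices:
    aw: float
    effort: float
    choice_beta: float
    choice_gamma: float
    valence_v1: float
    valence_v2: float
    valence_v3: float
    valence_v4: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def _asymmetry_ratio(right: float, left: float, what: str) -> float:
    if right < 0 or left < 0:
        raise ValidationError(f"{what}: band powers must be non-negative")
    denom = right + left
    if denom == 0:
        raise DegenerateInputError(f"{what}: zero total power")
    return (right - left) / denom


def aw_index(alpha_f4: float, alpha_f3: float) -> float:
    """Frontal alpha asymmetry (approach-withdrawal marker), in [-1, 1]."""
    return _asymmetry_ratio(alpha_f4, alpha_f3, "aw_index")


def effort_index(theta_f4: float, theta_f3: float) -> float:
    """Frontal theta asymmetry (cognitive-effort marker), in [-1, 1]."""
    return _asymmetry_ratio(theta_f4, theta_f3, "effort_index")


def choice_index(power_af3: float, power_af4: float) -> float:
    """Prefrontal log-power asymmetry (decision marker) for one band."""
    if power_af3 <= 0 or power_af4 <= 0:
        raise ValidationError("choice_index: band powers must be positive")
    la, lb = math.log(power_af3), math.log(power_af4)
    denom = la + lb
    if denom == 0:
        raise DegenerateInputError("choice_index: zero log-power sum")
    return (la - lb) / denom


def _pair_power(bp: BandPowerSet, band: str, pair: tuple[str, str]) -> float:
    return (bp.get(pair[0], band) + bp.get(pair[1], band)) / 2.0


def valence_indices(bp: BandPowerSet) -> tuple[float, float, float, float]:
    """The four valence variants from a frontal band-power set."""
    beta_l = _pair_power(bp, "beta", _LEFT_PAIR)
    beta_r = _pair_power(bp, "beta", _RIGHT_PAIR)
    alpha_l = _pair_power(bp, "alpha", _LEFT_PAIR)
    alpha_r = _pair_power(bp, "alpha", _RIGHT_PAIR)
    if alpha_l == 0 or alpha_r == 0:
        raise DegenerateInputError("valence v1: zero alpha pair power")
    v1 = beta_l / alpha_l - beta_r / alpha_r
    if alpha_l <= 0 or alpha_r <= 0:
        raise DegenerateInputError("valence v2: non-positive alpha pair power")
    v2 = math.log(alpha_l) - math.log(alpha_r)
    v3 = bp.get("F4", "alpha") - bp.get("F3", "beta")
    beta_f4 = bp.get("F4", "beta")
    beta_f3 = bp.get("F3", "beta")
    if beta_f4 == 0 or beta_f3 == 0:
        raise DegenerateInputError("valence v4: zero beta power")
    v4 = bp.get("F4", "alpha") / beta_f4 - bp.get("F3", "alpha") / beta_f3
    return v1, v2, v3, v4


def indices_from_band_powers(bp: BandPowerSet) -> PreferenceIndices:
    """All eight index values from a frontal band-power set."""
    v1, v2, v3, v4 = valence_indices(bp)
    return PreferenceIndices(
        aw=aw_index(bp.get("F4", "alpha"), bp.get("F3", "alpha")),
        effort=effort_index(bp.get("F4", "theta"), bp.get("F3", "theta")),
        choice_beta=choice_index(bp.get("AF3", "beta"), bp.get("AF4", "beta")),
        choice_gamma=choice_index(bp.get("AF3", "gamma"), bp.get("AF4", "gamma")),
        valence_v1=v1, valence_v2=v2, valence_v3=v3, valence_v4=v4,
    )


def all_indices_trial(epoch: TrialEpoch,
                      params: FeatureParams | None = None) -> PreferenceIndices:
    """Compute all eight indices for one epoch via Welch band powers.

    Only the frontal electrodes AF3, F3, AF4, F4 enter the calculation.
    """
    params = params or FeatureParams()
    frontal = ["AF3", "F3", "AF4", "F4"]
    bp = band_powers(epoch, params, channels=frontal)
    return indices_from_band_powers(bp)


def index_table(epochs: Sequence[TrialEpoch],
                params: FeatureParams | None = None) -> pd.DataFrame:
    """Per-trial index values with subject/stimulus/label key columns."""
    rows = []
    for ep in epochs:
        row = {
            "subject_id": ep.subject_id,
            "stimulus_id": ep.stimulus_id,
            "subjective_label": ep.subjective_label,
        }
        row.update(all_indices_trial(ep, params).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def valence_to_ninepoint(values: Iterable[float]) -> np.ndarray:
    """Affine min-max rescale onto [1, 9], rounded half-up to integer ranks."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2 or v.max() == v.min():
        raise DegenerateInputError(
            "need >= 2 distinct valence values to define ranks")
    scaled = 1.0 + 8.0 * (v - v.min()) / (v.max() - v.min())
    return np.floor(scaled + 0.5).astype(int)


def ninepoint_to_label(rank: int) -> str:
    """Ranks 1-5 map to dislike, 6-9 to like."""
    if not 1 <= rank <= 9:
        raise ValidationError(f"rank {rank} outside [1, 9]")
    return "like" if rank >= 6 else "dislike"


def valence_labels(table: pd.DataFrame, variant: str = "valence_v1",
                   per_subject: bool = True) -> pd.Series:
    """Valence-based like/dislike labels from a per-trial index table.

    The chosen valence variant is rescaled to 1-9 ranks within each subject
    (or pooled) and thresholded between ranks 5 and 6.
    """
    if variant not in table.columns:
        raise ValidationError(f"unknown valence variant {variant!r}")
    out = pd.Series(index=table.index, dtype=object)
    groups = table.groupby("subject_id").groups.values() if per_subject \
        else [table.index]
    for idx in groups:
        ranks = valence_to_ninepoint(table.loc[idx, variant])
        out.loc[idx] = [ninepoint_to_label(r) for r in ranks]
    return out


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Chance-corrected agreement between two categorical labelings.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the raters' marginal frequencies.
    """
    a = np.asarray(list(labels_a))
    b = np.asarray(list(labels_b))
    if a.size == 0 or a.shape != b.shape:
        raise ValidationError("need equal-length non-empty label vectors")
    cats = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = float(sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats))
    if p_e == 1.0:
        raise DegenerateInputError("both labelings constant: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)
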