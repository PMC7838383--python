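import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropref.core_io import TrialEpoch, ValidationError
from neuropref.features_psd import BandPowerSet
from neuropref.preference_indices import (
    DegenerateInputError,
    INDEX_NAMES,
    all_indices_trial,
    aw_index,
    choice_index,
    cohens_kappa,
    effort_index,
    index_table,
    indices_from_band_powers,
    ninepoint_to_label,
    valence_indices,
    valence_labels,
    valence_to_ninepoint,
)

BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0),
         "beta": (13.0, 30.0), "gamma": (30.0, 40.0)}


def _bp(af3, f3, af4, f4):
    """BandPowerSet from per-channel {band: power} dicts."""
    return BandPowerSet(
        {"AF3": af3, "F3": f3, "AF4": af4, "F4": f4}, BANDS)


def _uniform_bp(overrides=None):
    base = {b: 1.0 for b in BANDS}
    chans = {ch: dict(base) for ch in ("AF3", "F3", "AF4", "F4")}
    for (ch, band), val in (overrides or {}).items():
        chans[ch][band] = val
    return BandPowerSet(chans, BANDS)


positive = st.floats(0.01, 1e3)


class TestAsymmetryIndices:
    @pytest.mark.parametrize("f4,f3,expected", [
        (2.0, 2.0, 0.0), (3.0, 1.0, 0.5), (0.0, 5.0, -1.0)])
    def test_aw_closed_forms(self, f4, f3, expected):
        assert aw_index(f4, f3) == pytest.approx(expected)

    @pytest.mark.parametrize("f4,f3,expected", [
        (1.0, 1.0, 0.0), (1.0, 3.0, -0.5), (4.0, 0.0, 1.0)])
    def test_effort_closed_forms(self, f4, f3, expected):
        assert effort_index(f4, f3) == pytest.approx(expected)

    def test_zero_denominator_degenerate(self):
        with pytest.raises(DegenerateInputError):
            aw_index(0.0, 0.0)

    @given(positive, positive)
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_antisymmetric(self, a, b):
        v = aw_index(a, b)
        assert -1.0 <= v <= 1.0
        assert aw_index(b, a) == pytest.approx(-v, rel=1e-9, abs=1e-12)

    @given(positive, positive, st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, a, b, c):
        assert aw_index(c * a, c * b) == pytest.approx(aw_index(a, b),
                                                       rel=1e-9, abs=1e-12)


class TestChoiceIndex:
    def test_equal_logs_zero(self):
        assert choice_index(math.e, math.e) == pytest.approx(0.0)

    def test_e_squared_over_e(self):
        assert choice_index(math.e**2, math.e) == pytest.approx(1 / 3)

    def test_unit_numerator_power(self):
        # log(1)=0, log(e)=1: (0-1)/(0+1) = -1
        assert choice_index(1.0, math.e) == pytest.approx(-1.0)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValidationError):
            choice_index(0.0, 1.0)

    def test_zero_log_sum_degenerate(self):
        with pytest.raises(DegenerateInputError):
            choice_index(math.e, 1 / math.e)


class TestValence:
    def test_symmetric_powers_give_zero(self):
        v1, v2, v3, v4 = valence_indices(_uniform_bp())
        assert v1 == pytest.approx(0.0)
        assert v2 == pytest.approx(0.0)
        assert v4 == pytest.approx(0.0)

    def test_v3_zero_when_alpha_f4_equals_beta_f3(self):
        bp = _uniform_bp({("F4", "alpha"): 2.5, ("F3", "beta"): 2.5})
        assert valence_indices(bp)[2] == pytest.approx(0.0)

    def test_v2_log_ratio(self):
        bp = _uniform_bp({("AF3", "alpha"): 2.0, ("F3", "alpha"): 2.0})
        assert valence_indices(bp)[1] == pytest.approx(math.log(2.0))

    def test_left_right_swap_flips_signs(self, rng):
        chans = {ch: {b: rng.uniform(0.5, 3.0) for b in BANDS}
                 for ch in ("AF3", "F3", "AF4", "F4")}
        bp = BandPowerSet(chans, BANDS)
        swapped = BandPowerSet(
            {"AF3": chans["AF4"], "F3": chans["F4"],
             "AF4": chans["AF3"], "F4": chans["F3"]}, BANDS)
        v = valence_indices(bp)
        w = valence_indices(swapped)
        for i in (0, 1, 3):  # v1, v2, v4 are pure left-right contrasts
            assert w[i] == pytest.approx(-v[i], rel=1e-9, abs=1e-12)

    def test_eight_named_indices(self, canonical_epoch):
        idx = all_indices_trial(canonical_epoch)
        assert tuple(idx.as_dict()) == INDEX_NAMES

    def test_mirrored_trial_aw_vanishes(self, canonical_epoch):
        rec = canonical_epoch.recording
        data = rec.data.copy()
        m = rec.montage
        for left, right in (("AF3", "AF4"), ("F3", "F4")):
            data[m.index(right)] = data[m.index(left)]
        mirrored = TrialEpoch(rec.copy_with(data=data), stimulus_id="m")
        assert abs(all_indices_trial(mirrored).aw) < 1e-9


class TestNinepointLabeling:
    def test_endpoints_and_midpoint(self):
        ranks = valence_to_ninepoint([0.0, 0.5, 1.0])
        assert list(ranks) == [1, 5, 9]

    def test_cohort_0_1_2(self):
        assert list(valence_to_ninepoint([0.0, 1.0, 2.0])) == [1, 5, 9]

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            valence_to_ninepoint([1.0, 1.0, 1.0])

    @pytest.mark.parametrize("rank,label", [
        (1, "dislike"), (5, "dislike"), (6, "like"), (9, "like")])
    def test_threshold_between_5_and_6(self, rank, label):
        assert ninepoint_to_label(rank) == label

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValidationError):
            ninepoint_to_label(0)

    def test_valence_labels_per_subject(self, small_synth):
        epochs, _, truth = small_synth
        table = index_table(epochs)
        labels = valence_labels(table, "valence_v1")
        assert set(labels) <= {"like", "dislike"}
        # strong planted effect: valence labels track latent truth
        agree = np.mean(labels.to_numpy() == truth.latent_labels)
        assert agree > 0.8


class TestCohensKappa:
    def test_perfect_agreement(self):
        labs = ["like", "dislike", "like", "dislike"]
        assert cohens_kappa(labs, labs) == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # 2x2 confusion [[20, 5], [10, 15]]: p_o=0.7, p_e=0.5, kappa=0.4
        a = ["like"] * 25 + ["dislike"] * 25
        b = ["like"] * 20 + ["dislike"] * 5 + ["like"] * 10 + ["dislike"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_independent_labels_near_zero(self, rng):
        a = rng.choice(["like", "dislike"], size=10_000)
        b = rng.choice(["like", "dislike"], size=10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_both_constant_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cohens_kappa(["like"] * 5, ["like"] * 5)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        a = rng.choice(["like", "dislike"], size=200, p=[0.7, 0.3])
        b = np.where(rng.random(200) < 0.8, a,
                     rng.choice(["like", "dislike"], size=200))
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))


def test_valence_truth_agreement_monotone_in_effect():
    from neuropref.synthetic_eeg import SynthConfig, synth_dataset
    agree = []
    for d in (0.0, 2.0):
        cfg = SynthConfig(n_subjects=3, trials_per_subject=20, seed=31,
                          asymmetry_effect=d, noise_sd=1.0)
        epochs, _, truth = synth_dataset(cfg)
        table = index_table(epochs)
        labels = valence_labels(table, "valence_v1")
        agree.append(np.mean(labels.to_numpy() == truth.latent_labels))
    assert agree[1] >= agree[0]
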