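"""Descriptor correctness against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from moonpep import (FEATURE_NAMES, WindowParams, featurize, helical_content,
                     hydrophobic_moment, isoelectric_point, logp_octanol,
                     mean_charge, mean_hydrophobicity, net_charge,
                     residue_counts, window_range)
from moonpep.scales import (ACIDIC_RESIDUES, AMINO_ACIDS, BASIC_RESIDUES,
                            DEFAULT_SCALES)

from conftest import random_sequences

TAT_NEP = "YGRKKRRQRRRFFG"
TAT_NEP_NOCPP = "YGRKKRRQRRRFFGFLADDDDEE"

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


# ---------------------------------------------------------------- oracles

def oracle_charge(seq, pH):
    """Independent per-group Henderson-Hasselbalch sum."""
    total = 0.0
    for r in seq:
        if r in BASIC_RESIDUES:
            total += 1.0 / (1.0 + 10.0 ** (pH - DEFAULT_SCALES.pka[r]))
        if r in ACIDIC_RESIDUES:
            total -= 1.0 / (1.0 + 10.0 ** (DEFAULT_SCALES.pka[r] - pH))
    return total


def oracle_pi_grid(seq, step=1e-4):
    """Grid scan for the pH of minimal |charge| (vectorized)."""
    grid = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(grid)
    for r in seq:
        if r in BASIC_RESIDUES:
            charge += 1.0 / (1.0 + 10.0 ** (grid - DEFAULT_SCALES.pka[r]))
        if r in ACIDIC_RESIDUES:
            charge -= 1.0 / (1.0 + 10.0 ** (DEFAULT_SCALES.pka[r] - grid))
    return grid[np.argmin(np.abs(charge))]


def oracle_moment(seq, delta_deg=100.0):
    """Complex-exponential form of the per-residue hydrophobic moment."""
    z = sum(DEFAULT_SCALES.hydrophobicity[r]
            * np.exp(1j * math.radians(delta_deg) * k)
            for k, r in enumerate(seq))
    return abs(z) / len(seq)


# ------------------------------------------------------------------ counts

class TestResidueCounts:
    def test_tat_nep_composition(self):
        counts = dict(zip(AMINO_ACIDS, residue_counts(TAT_NEP)))
        assert counts["R"] == 6 and counts["K"] == 2
        assert counts["G"] == 2 and counts["F"] == 2
        assert counts["Q"] == 1 and counts["Y"] == 1
        assert sum(counts.values()) == 14

    @given(seq_strategy)
    def test_counts_sum_to_length_and_permutation_invariant(self, seq):
        c = residue_counts(seq)
        assert c.sum() == len(seq)
        shuffled = "".join(sorted(seq))
        assert np.array_equal(c, residue_counts(shuffled))


# ----------------------------------------------------------- hydrophobicity

class TestMeanHydrophobicity:
    @pytest.mark.parametrize("aa", list("ARWD"))
    def test_homopolymer_equals_scale_value(self, aa):
        assert mean_hydrophobicity(aa * 7) == pytest.approx(
            DEFAULT_SCALES.hydrophobicity[aa])

    def test_two_residue_average(self):
        h = DEFAULT_SCALES.hydrophobicity
        assert mean_hydrophobicity("AG") == pytest.approx((h["A"] + h["G"]) / 2)

    def test_tat_nep_against_sum_oracle(self):
        expected = sum(DEFAULT_SCALES.hydrophobicity[r] for r in TAT_NEP) / 14
        assert mean_hydrophobicity(TAT_NEP) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.1021428571428573, abs=1e-9)


# ------------------------------------------------------------------ charge

class TestCharge:
    def test_acid_base_pair_neutral_at_pka_midpoint(self):
        mid = (DEFAULT_SCALES.pka["D"] + DEFAULT_SCALES.pka["K"]) / 2
        assert net_charge("DK", pH=mid) == pytest.approx(0.0, abs=1e-12)

    def test_no_ionizable_groups_is_zero_everywhere(self):
        for pH in (0.0, 3.3, 7.0, 11.2, 14.0):
            assert net_charge("GGGG", pH=pH) == 0.0

    def test_tat_nep_close_to_plus_eight(self):
        got = net_charge(TAT_NEP, pH=7.0)
        assert got == pytest.approx(oracle_charge(TAT_NEP, 7.0), abs=1e-12)
        assert got == pytest.approx(8.0, abs=0.01)

    def test_ph_out_of_range(self):
        with pytest.raises(ValueError):
            net_charge("DK", pH=-0.5)

    def test_mean_charge_table1_values(self):
        assert mean_charge(TAT_NEP) == pytest.approx(
            oracle_charge(TAT_NEP, 7.0) / 14, abs=1e-12)
        assert mean_charge(TAT_NEP) == pytest.approx(0.5713, abs=1e-4)
        # the DDDDEE extension collapses the mean charge toward zero
        assert mean_charge(TAT_NEP_NOCPP) == pytest.approx(0.0872, abs=1e-4)

    @given(seq_strategy, st.sampled_from("DE"))
    def test_appending_acid_strictly_decreases_mean_charge(self, seq, acid):
        assert mean_charge(seq + acid) < mean_charge(seq)


class TestIsoelectricPoint:
    def test_one_acid_one_base_closed_form(self):
        expected = (DEFAULT_SCALES.pka["D"] + DEFAULT_SCALES.pka["K"]) / 2
        assert isoelectric_point("DK", tol=1e-6) == pytest.approx(
            expected, abs=1e-4)

    def test_monotone_positive_sequence_is_degenerate(self):
        pi, degenerate = isoelectric_point("RRRR", return_flag=True)
        assert degenerate
        assert pi == 14.0  # endpoint with the smaller |charge|

    def test_matches_grid_scan_oracle(self, rng):
        for seq in random_sequences(rng, 40):
            got = isoelectric_point(seq, tol=1e-4)
            want = oracle_pi_grid(seq)
            assert got == pytest.approx(want, abs=2e-4), seq


# ------------------------------------------------------------------ moment

class TestHydrophobicMoment:
    def test_18mer_homopolymer_cancels(self):
        # 18 unit vectors at 100 deg/residue land on every multiple of
        # 20 deg and sum to zero
        assert hydrophobic_moment("L" * 18) == pytest.approx(0.0, abs=1e-10)

    def test_zero_angle_degenerates_to_absolute_mean(self):
        seq = "LKKLLKLL"
        assert hydrophobic_moment(seq, delta_angle=0.0) == pytest.approx(
            abs(mean_hydrophobicity(seq)), abs=1e-12)

    def test_amphipathic_window_matches_complex_sum_oracle(self, rng):
        for seq in ["LKKLLKLLKKLL"] + random_sequences(rng, 30, 2, 25):
            assert hydrophobic_moment(seq) == pytest.approx(
                oracle_moment(seq), rel=1e-10, abs=1e-12)

    def test_window_shorter_than_two_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_moment("A")


# ----------------------------------------------------------- window ranges

class TestWindowRange:
    def test_homopolymer_range_is_zero(self):
        assert window_range("K" * 30, "charge") == 0.0
        assert window_range("K" * 30, "hydrophobic_moment") == 0.0

    def test_charge_blocks_against_enumeration_oracle(self):
        seq = "K" * 11 + "D" * 11
        got = window_range(seq, "charge")
        windows = [seq[i:i + 11] for i in range(len(seq) - 10)]
        charges = [oracle_charge(w, 7.0) for w in windows]
        assert got == pytest.approx(max(charges) - min(charges), abs=1e-12)
        # extremes are the all-K and all-D windows
        assert got == pytest.approx(
            oracle_charge("K" * 11, 7.0) - oracle_charge("D" * 11, 7.0),
            abs=1e-12)

    def test_moment_against_enumeration_oracle(self, rng):
        for seq in random_sequences(rng, 15, 12, 40):
            got = window_range(seq, "hydrophobic_moment")
            windows = [seq[i:i + 11] for i in range(len(seq) - 10)]
            moments = [oracle_moment(w) for w in windows]
            assert got == pytest.approx(max(moments) - min(moments), abs=1e-10)

    def test_short_sequence_single_window_rule(self):
        assert window_range("KDKDK", "charge") == 0.0
        assert window_range("KDKDK", "hydrophobic_moment") == 0.0


# ----------------------------------------------------- logP and helicity

class TestLogPAndHelicity:
    @pytest.mark.parametrize("aa, n", [("W", 5), ("D", 9)])
    def test_logp_linearity_on_homopolymers(self, aa, n):
        assert logp_octanol(aa * n) == pytest.approx(
            n * DEFAULT_SCALES.logp_octanol[aa], abs=1e-12)

    def test_logp_tat_nep_oracle_sum(self):
        expected = sum(DEFAULT_SCALES.logp_octanol[r] for r in TAT_NEP)
        assert logp_octanol(TAT_NEP) == pytest.approx(expected, abs=1e-12)

    def test_helix_former_extremes(self):
        assert helical_content("A" * 10) == 1.0
        assert helical_content("G" * 10) == 0.0

    def test_helicity_tat_nep_count_oracle(self):
        formers = sum(1 for r in TAT_NEP
                      if DEFAULT_SCALES.helix_propensity[r] >= 1.0)
        assert helical_content(TAT_NEP) == pytest.approx(formers / 14)
        assert formers == 5  # K,K,Q,F,F


# --------------------------------------------------------------- featurize

class TestFeaturize:
    def test_deterministic_and_consistent_with_counts(self):
        v1 = featurize(TAT_NEP)
        v2 = featurize(TAT_NEP)
        assert np.array_equal(v1, v2)
        assert np.array_equal(v1[:20], residue_counts(TAT_NEP))
        assert len(v1) == len(FEATURE_NAMES) == 27

    def test_all_entries_finite_on_random_sweep(self, rng):
        for seq in random_sequences(rng, 1000):
            v = featurize(seq)
            assert np.all(np.isfinite(v)), seq
            assert v[:20].sum() == len(seq)
            assert 0.0 <= v[26] <= 1.0
            assert v[23] >= 0.0 and v[24] >= 0.0
            assert 0.0 <= v[22] <= 14.0

    def test_permutation_invariance_structure(self, rng):
        # global descriptors ignore order; window ranges generally do not
        seq = "KKKKKKKKKKKDDDDDDDDDDD"
        perm = "KD" * 11
        v, w = featurize(seq), featurize(perm)
        invariant = list(range(23)) + [25, 26]
        assert np.allclose(v[invariant], w[invariant])
        assert not np.isclose(v[23], w[23])  # charge range differs

    def test_window_params_validation(self):
        with pytest.raises(ValueError):
            WindowParams(width=1)
        with pytest.raises(ValueError):
            WindowParams(delta_angle=360.0)
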