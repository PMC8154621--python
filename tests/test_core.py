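"""Unit and property tests for the sum-over-states core and the GFSM."""

import numpy as np
import pytest

from gfsm.core import (
    ElectronicStateSet,
    ResonanceError,
    TERM_CONSTANT,
    channel_classification,
    fsm_delta,
    full_sos_delta,
    gfsm_term,
    rotational_average,
    second_order_moment,
    term_label,
)
from gfsm.synthetic import flip_state_sign, random_rotation

from conftest import random_hermitian_system


# ---------------------------------------------------------------- state sets


class TestElectronicStateSet:
    def test_rejects_nonzero_ground_energy(self):
        with pytest.raises(ValueError, match="ground-state"):
            ElectronicStateSet(np.array([0.1, 0.2]), np.zeros((2, 2, 3)))

    def test_rejects_nonpositive_excited_energy(self):
        with pytest.raises(ValueError, match="positive"):
            ElectronicStateSet(np.array([0.0, -0.1]), np.zeros((2, 2, 3)))

    def test_hermitian_requires_symmetric_dipoles(self):
        mu = np.zeros((2, 2, 3))
        mu[0, 1] = (0, 0, 1.0)  # mirror missing
        with pytest.raises(ValueError, match="symmetric"):
            ElectronicStateSet(np.array([0.0, 0.1]), mu)

    def test_parity_forbids_same_parity_dipoles(self):
        mu = np.zeros((3, 3, 3))
        mu[0, 2] = mu[2, 0] = (0, 0, 1.0)  # gerade-gerade
        with pytest.raises(ValueError, match="parity"):
            ElectronicStateSet(
                np.array([0.0, 0.1, 0.2]), mu, parity=("g", "u", "g")
            )

    def test_from_pairs_hermitian_completion(self):
        s = ElectronicStateSet.from_pairs([0.0, 0.1], {(0, 1): (1.0, 0, 0)})
        assert np.allclose(s.dipoles_right[1, 0], (1.0, 0, 0))

    def test_fluctuation_shift_zeroes_ground_diagonal(self):
        s = ElectronicStateSet.from_pairs(
            [0.0, 0.1],
            {(0, 1): (0, 0, 1.0), (0, 0): (0.5, 0, 0), (1, 1): (0.5, 0, 2.0)},
        )
        shifted = s.with_fluctuation_dipoles()
        assert np.allclose(shifted.dipoles_right[0, 0], 0.0)
        assert np.allclose(shifted.dipoles_right[1, 1], (0, 0, 2.0))


# ------------------------------------------------- second-order moments


class TestSecondOrderMoment:
    def test_zero_dipoles_give_zero_tensor(self):
        s = ElectronicStateSet(np.array([0.0, 0.1, 0.3]), np.zeros((3, 3, 3)))
        assert np.allclose(second_order_moment(s, 2).single(), 0.0)

    def test_two_level_hand_value(self, two_level_system):
        # single intermediate: S_zz = (1*2 + 2*1)/(0.1 - 0.05) = 80 au
        S = second_order_moment(two_level_system, 1).single()
        expected = np.zeros((3, 3))
        expected[2, 2] = 80.0
        assert np.allclose(S, expected)

    def test_tensor_is_symmetric(self, rng):
        s = random_hermitian_system(rng, 5)
        S = second_order_moment(s, 3).single()
        assert np.allclose(S, S.T)

    def test_left_equals_right_for_hermitian(self, rng):
        s = random_hermitian_system(rng, 4)
        SL = second_order_moment(s, 2, side="left").single()
        SR = second_order_moment(s, 2, side="right").single()
        assert np.array_equal(SL, SR)

    def test_ground_state_final_rejected(self, two_level_system):
        with pytest.raises(IndexError):
            second_order_moment(two_level_system, 0)
        with pytest.raises(IndexError):
            second_order_moment(two_level_system, 5)

    def test_resonance_guard(self):
        # E_1 exactly at half of E_2
        s = ElectronicStateSet(np.array([0.0, 0.1, 0.2]), np.zeros((3, 3, 3)))
        with pytest.raises(ResonanceError):
            second_order_moment(s, 2)


# -------------------------------------------------------- rotational average


class TestRotationalAverage:
    def test_identity_contraction(self):
        eye = np.eye(3)
        assert rotational_average(eye, eye) == pytest.approx(2.0)

    def test_zero_tensor(self):
        z = np.zeros((3, 3))
        assert rotational_average(z, z) == 0.0

    def test_single_element_continues_hand_chain(self):
        S = np.zeros((3, 3))
        S[2, 2] = 80.0
        assert rotational_average(S, S) == pytest.approx(2560.0)

    def test_hermitian_nonnegative(self, rng):
        for _ in range(50):
            A = rng.normal(size=(3, 3))
            S = A + A.T
            assert rotational_average(S, S) >= 0.0

    def test_rejects_nonfinite(self):
        bad = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            rotational_average(bad, bad)


# ------------------------------------------------------------ full SOS delta


class TestFullSosDelta:
    def test_two_level_hand_value(self, two_level_system):
        assert full_sos_delta(two_level_system, 1) == pytest.approx(2560.0)

    def test_parity_selection_rule(self, rng):
        # final state of opposite parity to the ground state: every pathway
        # 0 -> K -> J would require K of both parities at once
        from gfsm.synthetic import SyntheticSpec, make_system

        for seed in range(10):
            q = make_system(SyntheticSpec("quadrupolar", seed=seed, n_excited=4))
            assert full_sos_delta(q, 1) == 0.0
            assert full_sos_delta(q, 3) == 0.0
            assert full_sos_delta(q, 2) > 0.0

    def test_quartic_dipole_scaling(self, rng):
        s = random_hermitian_system(rng, 5)
        scaled = ElectronicStateSet(s.energies, 2.0 * s.dipoles_right)
        assert full_sos_delta(scaled, 2) == pytest.approx(
            16.0 * full_sos_delta(s, 2), rel=1e-12
        )


# ---------------------------------------------------------------- GFSM terms


class TestGfsmTerm:
    def _single_intermediate_system(self, mu_0i, mu_ij):
        """3-state system where only the (I, I) = (1, 1) term can contribute:
        no 0->J coupling, no permanent dipoles, denominator E_1 - E_2/2 = 1."""
        return ElectronicStateSet.from_pairs(
            [0.0, 1.05, 0.1], {(0, 1): mu_0i, (1, 2): mu_ij}
        )

    def test_collinear_value_matches_sos_oracle(self):
        # full SOS of this construction is the independent oracle: S_zz = 2,
        # delta = (2/15)(4 + 4 + 4) = 1.6 au
        s = self._single_intermediate_system((0, 0, 1.0), (0, 0, 1.0))
        term = gfsm_term(s, 2, 1, 1)
        assert term.channels == pytest.approx((1.0, 1.0, 1.0))
        assert term.value == pytest.approx(1.6)
        assert term.value == pytest.approx(full_sos_delta(s, 2))

    def test_orthogonal_value_matches_sos_oracle(self):
        # only the self-angle channel survives; oracle value 8/15
        s = self._single_intermediate_system((0, 0, 1.0), (1.0, 0, 0))
        term = gfsm_term(s, 2, 1, 1)
        assert term.channels == pytest.approx((0.0, 1.0, 0.0))
        assert term.value == pytest.approx(8.0 / 15.0)
        assert term.value == pytest.approx(full_sos_delta(s, 2))

    def test_zero_dipole_gives_exact_zero(self):
        s = self._single_intermediate_system((0, 0, 1.0), (0, 0, 0.0))
        term = gfsm_term(s, 2, 1, 1)
        assert term.value == 0.0
        assert term.channels is None
        assert term.magnitude_prefactor == 0.0

    def test_value_consistent_with_prefactor_and_channels(self, rng):
        s = random_hermitian_system(rng, 4)
        term = gfsm_term(s, 3, 1, 2)
        assert term.value == pytest.approx(
            TERM_CONSTANT * term.magnitude_prefactor * sum(term.channels)
        )

    def test_index_error_outside_set(self, two_level_system):
        with pytest.raises(IndexError):
            gfsm_term(two_level_system, 1, 0, 5)

    def test_label(self):
        assert term_label(2, 1, 1) == "delta_0211"
        assert term_label(11, 0, 11) == "delta_0,11,0,11"


# ----------------------------------------------------------- FSM aggregation


class TestFsmDelta:
    def test_two_state_model_has_four_terms(self, two_level_system):
        r = fsm_delta(two_level_system, 1, ())
        assert r.model == "2SM"
        assert set(r.terms) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_three_state_model_has_nine_terms(self, rng):
        s = random_hermitian_system(rng, 4)
        r = fsm_delta(s, 2, (1,))
        assert r.model == "3SM"
        assert r.n_terms == 9
        assert set(r.terms) == {
            (K, L) for K in (0, 1, 2) for L in (0, 1, 2)
        }

    def test_total_is_sum_of_terms(self, rng):
        s = random_hermitian_system(rng, 5)
        r = fsm_delta(s, 2, (1, 3))
        assert r.total == pytest.approx(sum(t.value for t in r.terms.values()))

    def test_two_level_two_state_model_is_exact(self, two_level_system):
        # a two-level state space is complete, so 2SM == full SOS exactly
        assert fsm_delta(two_level_system, 1, ()).total == pytest.approx(
            full_sos_delta(two_level_system, 1), rel=1e-14
        )

    def test_cross_term_pair_coincides_for_hermitian(self, rng):
        s = random_hermitian_system(rng, 4)
        r = fsm_delta(s, 2, (1,))
        for (K, L), t in r.terms.items():
            assert t.value == pytest.approx(r.terms[(L, K)].value, rel=1e-12)

    def test_rejects_duplicate_or_trivial_intermediates(self, rng):
        s = random_hermitian_system(rng, 5)
        with pytest.raises(ValueError):
            fsm_delta(s, 2, (1, 1))
        with pytest.raises(ValueError):
            fsm_delta(s, 2, (0,))
        with pytest.raises(ValueError):
            fsm_delta(s, 2, (2,))

    def test_nsm_label(self, rng):
        s = random_hermitian_system(rng, 6)
        assert fsm_delta(s, 2, (1, 3, 4)).model == "NSM(5)"


# -------------------------------------------------- oracle and invariances


N_ENSEMBLE = 200


class TestSosOracleEnsemble:
    """All-states GFSM against the full sum over states, plus the exact
    invariances of the rotational average, on a 200-system random ensemble."""

    def _ensemble(self):
        rng = np.random.default_rng(1234)
        for _ in range(N_ENSEMBLE):
            s = random_hermitian_system(rng)
            J = int(rng.integers(1, s.n_states))
            yield s, J, rng

    def test_all_states_gfsm_equals_full_sos(self):
        for s, J, _ in self._ensemble():
            inter = tuple(i for i in range(1, s.n_states) if i != J)
            total = fsm_delta(s, J, inter).total
            ref = full_sos_delta(s, J)
            assert total == pytest.approx(ref, rel=1e-10, abs=1e-12)

    def test_rotation_invariance(self):
        for s, J, rng in self._ensemble():
            rot = random_rotation(s, int(rng.integers(0, 2**31)))
            assert full_sos_delta(rot, J) == pytest.approx(
                full_sos_delta(s, J), rel=1e-10, abs=1e-12
            )
            assert fsm_delta(rot, J, ()).total == pytest.approx(
                fsm_delta(s, J, ()).total, rel=1e-10, abs=1e-12
            )

    def test_state_phase_gauge_invariance(self):
        for s, J, rng in self._ensemble():
            K = int(rng.integers(0, s.n_states))
            flipped = flip_state_sign(s, K)
            assert full_sos_delta(flipped, J) == pytest.approx(
                full_sos_delta(s, J), rel=1e-10, abs=1e-12
            )

    def test_quartic_scaling(self):
        for s, J, _ in self._ensemble():
            scaled = ElectronicStateSet(s.energies, 3.0 * s.dipoles_right)
            assert full_sos_delta(scaled, J) == pytest.approx(
                81.0 * full_sos_delta(s, J), rel=1e-10, abs=1e-12
            )

    def test_hermitian_totals_nonnegative(self):
        for s, J, _ in self._ensemble():
            assert full_sos_delta(s, J) >= 0.0
            assert fsm_delta(s, J, ()).total >= -1e-12
            inter = next((i for i in range(1, s.n_states) if i != J), None)
            if inter is not None:
                assert fsm_delta(s, J, (inter,)).total >= -1e-12

    def test_diagonal_convention_totals_agree(self):
        # raw vs fluctuation diagonal dipoles: identical totals at the
        # degenerate photon energy, for SOS and every truncation
        for s, J, _ in self._ensemble():
            f = s.with_fluctuation_dipoles()
            assert full_sos_delta(f, J) == pytest.approx(
                full_sos_delta(s, J), rel=1e-9, abs=1e-10
            )
            assert fsm_delta(f, J, ()).total == pytest.approx(
                fsm_delta(s, J, ()).total, rel=1e-9, abs=1e-10
            )


# ------------------------------------------------------------ classification


class TestChannelClassification:
    def test_constructive_null_destructive(self):
        # raw-diagonal two-level system: the (0, J) cross term has a negative
        # denominator product, so with aligned dipoles it is destructive
        s = ElectronicStateSet.from_pairs(
            [0.0, 0.1],
            {(0, 1): (0, 0, 2.0), (0, 0): (0, 0, 1.0), (1, 1): (0, 0, 3.0)},
        )
        r = fsm_delta(s, 1, ())
        labels = channel_classification(r)
        assert labels[(1, 1)] == "constructive"
        assert labels[(0, 1)] == "destructive"
        assert labels[(1, 0)] == "destructive"
        # the destructive cross terms still leave the Hermitian total >= 0
        assert r.total >= 0.0

    def test_null_for_zero_terms(self, two_level_system):
        labels = channel_classification(fsm_delta(two_level_system, 1, ()))
        assert labels[(0, 0)] == "null"  # no ground-state permanent dipole

    def test_cross_term_sign_flipss_with_angle_sweep(self):
        # sweep the angle between mu01 and mu11; the (0, 1) cross term
        # changes sign when the channel sum does
        signs = []
        for theta in np.linspace(0.0, np.pi, 7):
            mu11 = (3.0 * np.sin(theta), 0.0, 3.0 * np.cos(theta))
            s = ElectronicStateSet.from_pairs(
                [0.0, 0.1],
                {(0, 1): (0, 0, 2.0), (0, 0): (0, 0, 1.0), (1, 1): mu11},
            )
            signs.append(np.sign(fsm_delta(s, 1, ()).terms[(0, 1)].value))
        assert -1.0 in signs and 1.0 in signs
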