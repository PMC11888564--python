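import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netpattern as npt
from netpattern.bifurcation import (
    DynamicsError,
    WrongClassifierError,
    brute_force_critical,
)
from netpattern.validate import (
    construct_1d_sweep,
    construct_detR_nonpositive_bifurcation,
    construct_hopf_bifurcation,
    construct_steady_bifurcation,
    prop2_trial,
    random_real_spectrum_network,
)


class TestBInvariant:
    def test_coupling_on_first_chemical_gives_d_kappa(self):
        # Q = [[a,b],[c,d]], R = [[kappa,0],[0,0]] -> B = d*kappa
        a, b, c, d, kappa = 1.3, -0.7, 2.1, -2.5, 0.9
        dyn = npt.LocalDynamics(
            np.array([[a, b], [c, d]]), np.array([[kappa, 0], [0, 0]])
        )
        assert npt.B_invariant(dyn) == pytest.approx(d * kappa)

    def test_cross_coupling_gives_minus_b_kappa(self):
        # R = [[0,0],[kappa,0]] -> B = -b*kappa
        a, b, c, d, kappa = 1.3, -0.7, 2.1, -2.5, 0.9
        dyn = npt.LocalDynamics(
            np.array([[a, b], [c, d]]), np.array([[0, 0], [kappa, 0]])
        )
        assert npt.B_invariant(dyn) == pytest.approx(-b * kappa)

    def test_lateral_inhibition_numeric_instance(self, notch_numeric):
        assert npt.B_invariant(notch_numeric) == pytest.approx(1.0)

    def test_lateral_inhibition_sign_pattern_positive(self, notch_signs):
        assert npt.B_invariant(notch_signs) == "+"

    def test_wrong_dimension(self):
        with pytest.raises(DynamicsError):
            npt.B_invariant(npt.LocalDynamics(np.array([[-1.0]]), np.array([[0.5]])))


class TestSyncStability:
    def test_scalar_stable(self, vpc_dec):
        dyn = npt.LocalDynamics(np.array([[-2.0]]), np.array([[0.5]]))
        rep = npt.sync_stability(dyn, vpc_dec)
        assert rep["stable"]
        # blocks at mu = -2 and mu = +2 give -3 and -1
        assert rep["margins"][0] == pytest.approx(3.0)
        assert rep["margins"][-1] == pytest.approx(1.0)
        assert rep["necessary_conditions"]["Q<0"]

    def test_scalar_marginal_at_mu1(self, vpc_dec):
        dyn = npt.LocalDynamics(np.array([[-1.0]]), np.array([[-0.5]]))
        rep = npt.sync_stability(dyn, vpc_dec)
        assert rep["binding_mu_index"] == 1
        assert rep["binding_margin"] == pytest.approx(0.0, abs=1e-12)

    def test_planar_stable(self, vpc_dec):
        dyn = npt.LocalDynamics(
            np.array([[-1.0, -1.0], [0.0, -1.0]]),
            np.array([[0.0, 0.0], [0.4, 0.0]]),
        )
        rep = npt.sync_stability(dyn, vpc_dec)
        assert rep["stable"]
        # det(Q + mu R) = 1 + 0.4 mu at mu = -2, +2 -> 0.2 and 1.8
        assert min(rep["margins"]) == pytest.approx(0.2)
        assert rep["necessary_conditions"]["tr Q<0"]

    def test_sign_only_rejected(self, notch_signs, vpc_dec):
        with pytest.raises(DynamicsError):
            npt.sync_stability(notch_signs, vpc_dec)


class TestClassify1d:
    def test_negative_coupling_breaks_synchrony(self):
        cls = npt.classify_1d(-0.3)
        assert cls.case_id == 2
        assert cls.pattern_space_label == "P_mu1" and cls.synchrony_breaking

    def test_positive_coupling_preserves_synchrony(self):
        cls = npt.classify_1d(0.3)
        assert cls.case_id == 3
        assert cls.pattern_space_label == "P_muk" and not cls.synchrony_breaking

    def test_zero_coupling_all_critical(self):
        cls = npt.classify_1d(0.0)
        assert cls.case_id == 1 and cls.pattern_space_label == "R^n"

    def test_sign_characters(self):
        assert npt.classify_1d("-").case_id == 2
        assert npt.classify_1d("+").case_id == 3


class TestClassifyTable:
    def test_lateral_inhibition_signs_select_row_one(self, notch_signs, vpc_dec):
        cls = npt.classify_2d_detR_zero(notch_signs, vpc_dec)
        assert cls.case_id == 1
        assert cls.pattern_space_label == "P_mu1"
        assert cls.eig_type == "real"
        assert cls.synchrony_breaking and not cls.degenerate
        assert cls.eigenspace_dim_value == vpc_dec.geo_mult[0] == 1

    def test_numeric_steady_rows(self, vpc_dec):
        rng = np.random.default_rng(0)
        row1 = construct_steady_bifurcation(vpc_dec, rng, at_mu1=True)
        assert npt.classify_2d_detR_zero(row1, vpc_dec).case_id == 1
        row3 = construct_steady_bifurcation(vpc_dec, rng, at_mu1=False)
        cls3 = npt.classify_2d_detR_zero(row3, vpc_dec)
        assert cls3.case_id == 3 and not cls3.synchrony_breaking

    def test_numeric_hopf_rows(self, vpc_dec):
        rng = np.random.default_rng(1)
        row2 = construct_hopf_bifurcation(vpc_dec, rng, at_mu1=True)
        cls2 = npt.classify_2d_detR_zero(row2, vpc_dec)
        assert cls2.case_id == 2 and cls2.eig_type == "imaginary"
        row4 = construct_hopf_bifurcation(vpc_dec, rng, at_mu1=False)
        cls4 = npt.classify_2d_detR_zero(row4, vpc_dec)
        assert cls4.case_id == 4 and cls4.pattern_space_label == "P_muk"

    def test_nonzero_detR_routed_away(self, vpc_dec):
        dyn = npt.LocalDynamics(-np.eye(2), np.array([[0.3, 0.0], [0.0, 0.2]]))
        with pytest.raises(WrongClassifierError):
            npt.classify_2d_detR_zero(dyn, vpc_dec)


class TestDetRNonpositive:
    def test_admissible_set(self, notch_signs, vpc_dec):
        rep = npt.classify_2d_detR_nonpositive(notch_signs, vpc_dec)
        assert rep["admissible"] == {"P_mu1", "P_muk", "P_mu1 ⊕ P_muk", "R^n"}

    def test_negative_determinant_critical_is_extreme(self, vpc_dec):
        rng = np.random.default_rng(3)
        found = 0
        while found < 5:
            dyn = construct_detR_nonpositive_bifurcation(vpc_dec, rng)
            if dyn is None:
                continue
            found += 1
            bf = brute_force_critical(dyn, vpc_dec, tol=1e-5)
            assert bf["critical_indices"]
            assert set(bf["critical_indices"]) <= {1, vpc_dec.k}

    def test_positive_determinant_rejected(self, vpc_dec):
        dyn = npt.LocalDynamics(-np.eye(2), np.array([[0.3, 0.0], [0.0, 0.4]]))
        with pytest.raises(DynamicsError):
            npt.classify_2d_detR_nonpositive(dyn, vpc_dec)


class TestJacobianOracle:
    def test_two_node_closed_form(self):
        q, r = -1.7, 0.6
        dyn = npt.LocalDynamics(np.array([[q]]), np.array([[r]]))
        J, rep = npt.jacobian_full(dyn, np.array([[0, 1], [1, 0]]))
        assert np.allclose(J, [[q, r], [r, q]])
        assert sorted(ev.real for ev in rep["eig_full"]) == pytest.approx(
            [q - r, q + r]
        )

    def test_vpc_lateral_inhibition(self, notch_numeric, vpc):
        _, rep = npt.jacobian_full(notch_numeric, npt.adjacency_matrix(vpc))
        assert rep["multiset_distance"] < 1e-8

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 100_000))
    def test_block_eigenvalues_match_full_jacobian(self, seed):
        dist = prop2_trial(np.random.default_rng(seed))
        assert dist < 1e-6


class TestDesigner:
    @pytest.mark.parametrize("target", [1, 3, 6])
    def test_round_trip_on_vpc_spectrum(self, vpc_dec, target):
        dyn = npt.design_local_dynamics(vpc_dec, target)
        bf = brute_force_critical(dyn, vpc_dec)
        assert bf["critical_indices"] == [target]
        assert bf["critical_types"][target] == "real"
        # all block traces stay negative (steady-state criticality only)
        for mu in vpc_dec.eigenvalues:
            assert np.trace(dyn.Q + mu.real * dyn.R) < 0

    def test_interior_target_needs_positive_detR(self, vpc_dec):
        dyn = npt.design_local_dynamics(vpc_dec, 3)
        assert np.linalg.det(dyn.R) > 0

    def test_synchrony_preserving_endpoint(self, vpc_dec):
        dyn = npt.design_local_dynamics(vpc_dec, vpc_dec.k)
        bf = brute_force_critical(dyn, vpc_dec)
        assert bf["critical_indices"] == [vpc_dec.k]

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 100_000))
    def test_round_trip_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        _, dec = random_real_spectrum_network(rng)
        target = int(rng.integers(1, dec.k + 1))
        dyn = npt.design_local_dynamics(dec, target)
        bf = brute_force_critical(dyn, dec)
        assert bf["critical_indices"] == [target]


class TestSweeps:
    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 100_000), sign=st.sampled_from([-1, 0, 1]))
    def test_first_crossing_matches_scalar_rule(self, seed, sign):
        rng = np.random.default_rng(seed)
        _, dec = random_real_spectrum_network(rng)
        dyn = construct_1d_sweep(dec, rng, sign)
        bf = brute_force_critical(dyn, dec)
        cls = npt.classify_1d(dyn.R[0, 0])
        if sign == 0:
            assert bf["critical_indices"] == list(range(1, dec.k + 1))
            assert cls.case_id == 1
        elif sign < 0:
            assert bf["critical_indices"] == [1] and cls.case_id == 2
        else:
            assert bf["critical_indices"] == [dec.k] and cls.case_id == 3
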