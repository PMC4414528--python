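"""Unit tests for the transport model: carriers, fluxes, rhs, fixed point."""

import numpy as np
import pytest
from scipy import optimize

from auxring.model import (
    NumericsError,
    RingState,
    TransportParams,
    carrier_totals,
    dump_params,
    efflux_polarization,
    homogeneous_steady_state,
    load_params,
    membrane_fluxes,
    read_state_csv,
    rhs,
    write_state_csv,
)


def uniform_state(n, A, a):
    return RingState(np.full(n, float(A)), np.full(n, float(a)))


class TestCarrierTotals:
    @pytest.mark.parametrize("A,theta,expected", [
        (10.0, 10.0, (0.25, 0.5)),    # half-saturation point
        (0.0, 10.0, (0.0, 0.0)),      # no auxin, no induction
        (5.0, 0.0, (0.5, 1.0)),       # constant-carrier variant
        (0.0, 0.0, (0.5, 1.0)),       # constant variant also at A = 0
    ])
    def test_pointwise(self, A, theta, expected):
        p = TransportParams(theta_I=theta, theta_P=theta)
        i_tot, p_tot = carrier_totals(np.array([A]), p)
        assert i_tot[0] == pytest.approx(expected[0], abs=1e-15)
        assert p_tot[0] == pytest.approx(expected[1], abs=1e-15)

    def test_bounds_and_monotonicity(self):
        p = TransportParams()
        A = np.linspace(0, 1e4, 200)
        i_tot, p_tot = carrier_totals(A, p)
        assert np.all((i_tot >= 0) & (i_tot <= 0.5))
        assert np.all((p_tot >= 0) & (p_tot <= 1.0))
        assert np.all(np.diff(i_tot) >= 0) and np.all(np.diff(p_tot) >= 0)

    def test_negative_auxin_rejected(self):
        with pytest.raises(ValueError):
            carrier_totals(np.array([-1.0]), TransportParams())


class TestPolarization:
    def test_uniform_ring_splits_evenly(self):
        phi_l, phi_r = efflux_polarization(np.full(7, 4.2))
        assert np.allclose(phi_l, 0.5) and np.allclose(phi_r, 0.5)

    def test_all_carriers_face_the_loaded_neighbor(self):
        # cell 1 sees A=0 on the left, A=3 on the right
        A = np.array([0.0, 5.0, 3.0])
        phi_l, phi_r = efflux_polarization(A)
        assert phi_r[1] == pytest.approx(1.0)
        assert phi_l[1] == pytest.approx(0.0)

    def test_zero_neighbors_tie_rule(self):
        A = np.array([0.0, 5.0, 0.0])
        phi_l, phi_r = efflux_polarization(A)
        assert phi_l[1] == 0.5 and phi_r[1] == 0.5

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 50, 60)
        for n in (0.5, 1.0, 2.0):
            phi_l, phi_r = efflux_polarization(A, polarity_exponent=n)
            assert np.allclose(phi_l + phi_r, 1.0)
            assert np.all((phi_l >= 0) & (phi_l <= 1))


class TestMembraneFluxes:
    def test_no_transport_no_flux(self):
        p = TransportParams(E=0.0, I=0.0, D_ca=0.0)
        state = uniform_state(6, 3.0, 2.0)
        J_l, J_r = membrane_fluxes(state, p)
        assert np.all(J_l == 0) and np.all(J_r == 0)

    def test_inward_flux_linear_in_apoplastic_auxin(self):
        p = TransportParams(E=0.0)
        rng = np.random.default_rng(1)
        A = rng.uniform(1, 10, 8)
        a = rng.uniform(1, 10, 8)
        J_l1, J_r1 = membrane_fluxes(RingState(A, a), p)
        J_l2, J_r2 = membrane_fluxes(RingState(A, 2 * a), p)
        assert np.allclose(J_l2, 2 * J_l1) and np.allclose(J_r2, 2 * J_r1)

    def test_net_flux_vanishes_at_fixed_point(self):
        p = TransportParams()
        A_star, a_star = homogeneous_steady_state(p)
        J_l, J_r = membrane_fluxes(uniform_state(10, A_star, a_star), p)
        assert np.allclose(J_l + J_r, 0.0, atol=1e-12)

    def test_mismatched_lengths_rejected(self):
        from auxring.model import CarrierDistribution
        state = uniform_state(6, 1.0, 1.0)
        bad = CarrierDistribution(np.ones(4), np.ones(4), np.full(4, .5), np.full(4, .5))
        with pytest.raises(ValueError):
            membrane_fluxes(state, TransportParams(), bad)


class TestRhs:
    def test_transport_conserves_mass(self):
        p = TransportParams(sigma_c=0.0, nu_c=0.0)
        rng = np.random.default_rng(2)
        state = RingState(rng.uniform(0, 20, 60), rng.uniform(0, 20, 60))
        dA, da = rhs(state, p)
        assert dA.sum() + da.sum() / p.rho == pytest.approx(0.0, abs=1e-10)

    def test_rotation_equivariance(self):
        p = TransportParams()
        rng = np.random.default_rng(3)
        state = RingState(rng.uniform(1, 20, 12), rng.uniform(1, 20, 12))
        dA, da = rhs(state, p)
        for k in (1, 5):
            dAr, dar = rhs(RingState(np.roll(state.A, k), np.roll(state.a, k)), p)
            assert np.allclose(dAr, np.roll(dA, k), rtol=1e-12)
            assert np.allclose(dar, np.roll(da, k), rtol=1e-12)

    def test_mirror_equivariance(self):
        # reflection through cell 0: cell i -> -i, apoplast j -> -j-1
        p = TransportParams()
        rng = np.random.default_rng(4)
        n = 10
        state = RingState(rng.uniform(1, 20, n), rng.uniform(1, 20, n))
        idx = np.arange(n)
        refl_c = (-idx) % n
        refl_a = (-idx - 1) % n
        dA, da = rhs(state, p)
        dAm, dam = rhs(RingState(state.A[refl_c], state.a[refl_a]), p)
        assert np.allclose(dAm, dA[refl_c], rtol=1e-12)
        assert np.allclose(dam, da[refl_a], rtol=1e-12)

    def test_fixed_point_has_zero_derivative(self):
        p = TransportParams()
        A_star, a_star = homogeneous_steady_state(p)
        dA, da = rhs(uniform_state(60, A_star, a_star), p)
        assert max(np.abs(dA).max(), np.abs(da).max()) < 1e-10

    def test_non_finite_state_rejected(self):
        state = uniform_state(6, 1.0, 1.0)
        state.A[2] = np.nan
        with pytest.raises(NumericsError):
            rhs(state, TransportParams())


class TestHomogeneousSteadyState:
    def test_no_efflux_drains_apoplast(self):
        _, a_star = homogeneous_steady_state(TransportParams(E=0.0))
        assert a_star == 0.0

    def test_no_production_empty_ring(self):
        A_star, a_star = homogeneous_steady_state(TransportParams(sigma_c=0.0))
        assert A_star == 0.0 and a_star == 0.0

    def test_degradation_required(self):
        with pytest.raises(ValueError):
            homogeneous_steady_state(TransportParams(nu_c=0.0))

    def test_matches_damped_newton_oracle(self):
        # independent root-finder on the uniform-state reduction of rhs
        p = TransportParams()

        def uniform_rhs(x):
            dA, da = rhs(uniform_state(6, x[0], x[1]), p)
            return [dA[0], da[0]]

        sol = optimize.root(uniform_rhs, x0=[5.0, 5.0], method="lm")
        assert sol.success
        A_star, a_star = homogeneous_steady_state(p)
        assert A_star == pytest.approx(sol.x[0], rel=1e-8)
        assert a_star == pytest.approx(sol.x[1], rel=1e-8)


class TestIO:
    def test_params_roundtrip(self, tmp_path):
        p = TransportParams(I=0.5, D=7.0, theta_I=0.0)
        path = tmp_path / "params.yaml"
        dump_params(p, path)
        assert load_params(path) == p

    def test_empty_file_gives_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        assert load_params(path) == TransportParams()

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("influx_rate: 3.0\n")
        with pytest.raises(ValueError, match="influx_rate"):
            load_params(path)

    def test_state_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        state = RingState(rng.uniform(0, 10, 8), rng.uniform(0, 10, 8))
        path = tmp_path / "state.csv"
        write_state_csv(state, path, time=3.5)
        back = read_state_csv(path)
        assert np.allclose(back.A, state.A) and np.allclose(back.a, state.a)
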