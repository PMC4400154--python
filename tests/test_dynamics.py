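import numpy as np
import pytest
from scipy.integrate import odeint

from dlcact.dynamics import (
    DEFAULT_TRUE_PARAMS,
    EmbryoState,
    ModelParameters,
    initial_conditions,
    interphase_rhs,
    mitosis_rhs,
    mix_at_mitosis,
    resample_piecewise_constant,
    simulate,
    start_interphase,
    toll_rate,
)
from dlcact.geometry import build_schedule

from conftest import make_cycle


def params(**kw):
    return DEFAULT_TRUE_PARAMS.replace(**kw)


ZERO_RATES = dict(
    zeta_dl=0, xi_dl=0, zeta_dc=0, xi_dc=0, zeta_cact=0, xi_cact=0,
    lambda_dl=0, lambda_dc=0, lambda_cact=0,
)


class TestTollRate:
    def test_peak_at_ventral_midline(self):
        assert toll_rate(0.0, beta=2.0, phi_prime=0.1, beta0=0.3) == pytest.approx(2.3)

    def test_one_width_out(self):
        val = toll_rate(0.1, beta=2.0, phi_prime=0.1, beta0=0.3)
        assert val == pytest.approx(2.0 * np.exp(-0.5) + 0.3)

    def test_flat_without_toll_amplitude(self):
        z = np.linspace(0, 1, 11)
        assert np.allclose(toll_rate(z, 0.0, 0.1, 0.3), 0.3)

    def test_monotone_non_increasing(self):
        z = np.linspace(0, 1, 101)
        b = toll_rate(z, 1.7, 0.15, 0.01)
        assert np.all(np.diff(b) <= 1e-15)
        assert b[-1] == pytest.approx(0.01, abs=1e-6)


class TestInterphaseRhs:
    def test_empty_embryo_only_cact_production(self):
        cyc = make_cycle(n=3, V_C=2.0)
        z = cyc.dv_positions()
        y = np.zeros(3 * 6)
        dy = interphase_rhs(y, params(), cyc, z).reshape(3, 6)
        expect = np.zeros((3, 6))
        expect[:, 5] = 1.0 / 2.0  # dZ_cyt = production / V_C
        assert np.allclose(dy, expect)

    def test_dissociation_stoichiometry_single_compartment(self):
        p = params(**ZERO_RATES, alpha=0, beta=2.0, beta0=0.1, psi=0.5)
        cyc = make_cycle(n=1, V_C=4.0)
        z = cyc.dv_positions()  # z = 0.5
        state = EmbryoState(
            phase="interphase",
            U_nuc=np.zeros(1), U_cyt=np.zeros(1),
            W_nuc=np.zeros(1), W_cyt=np.ones(1),
            Z_nuc=np.zeros(1), Z_cyt=np.zeros(1),
        )
        z = np.array([0.0])  # place the compartment at the ventral midline
        bhat = toll_rate(0.0, 2.0, p.phi_prime, 0.1)
        dy = interphase_rhs(state.pack(), p, cyc, z).reshape(1, 6)[0]
        assert dy[1] == pytest.approx(bhat)       # dU_cyt = +beta_hat W
        assert dy[3] == pytest.approx(-bhat)      # dW_cyt = -beta_hat W
        assert dy[5] == pytest.approx(0.5 * bhat + 1.0 / 4.0)  # psi*bhat + prod

    def test_toll_acts_on_cytoplasmic_complex_only(self):
        # equal nuclear and cytoplasmic complex: the cytoplasmic pool
        # dissociates at beta_hat >> beta0, the nuclear pool at beta0 only
        p = params(**ZERO_RATES, beta=5.0, beta0=0.001)
        cyc = make_cycle(n=1)
        state = EmbryoState(
            phase="interphase",
            U_nuc=np.zeros(1), U_cyt=np.zeros(1),
            W_nuc=np.ones(1), W_cyt=np.ones(1),
            Z_nuc=np.zeros(1), Z_cyt=np.zeros(1),
        )
        z = np.array([0.0])  # ventral midline, where Toll peaks
        dy = interphase_rhs(state.pack(), p, cyc, z).reshape(1, 6)[0]
        dW_nuc, dW_cyt = dy[2], dy[3]
        assert abs(dW_cyt) > 100 * abs(dW_nuc)

    def test_dimension_mismatch_rejected(self):
        cyc = make_cycle(n=3)
        with pytest.raises(ValueError):
            interphase_rhs(np.zeros(2 * 6), params(), cyc, cyc.dv_positions())


class TestMitosisRhs:
    def test_flat_profile_kills_diffusion(self):
        p = params(**{**ZERO_RATES, "lambda_dl": 3.0, "lambda_dc": 3.0,
                      "lambda_cact": 3.0},
                   beta=0.0, beta0=0.0, gamma=0.0, alpha=0.0)
        cyc = make_cycle(n=5, V_C=1.5)
        y = np.tile([0.7, 0.3, 0.2], 5)
        dy = mitosis_rhs(y, p, cyc, cyc.dv_positions()).reshape(5, 3)
        assert np.allclose(dy[:, :2], 0.0)
        assert np.allclose(dy[:, 2], 1.0 / cyc.prism_volume_tilde)

    def test_dissociation_per_position(self):
        p = params(**ZERO_RATES, alpha=0.0, beta=3.0, beta0=0.05)
        cyc = make_cycle(n=4)
        z = cyc.dv_positions()
        y = np.tile([0.0, 1.0, 0.0], 4)
        dy = mitosis_rhs(y, p, cyc, z).reshape(4, 3)
        assert np.allclose(dy[:, 0], toll_rate(z, 3.0, p.phi_prime, 0.05))

    def test_total_dl_conserved_by_cytoplasmic_equations(self):
        # summing the free-dl and complex equations kills reaction terms;
        # diffusion telescopes under no-flux boundaries
        rng = np.random.default_rng(0)
        p = params()
        cyc = make_cycle(n=6, V_C=2.0)
        y = rng.uniform(0, 1, size=6 * 3)
        dy = mitosis_rhs(y, p, cyc, cyc.dv_positions()).reshape(6, 3)
        total_rate = cyc.prism_volume_tilde * np.sum(dy[:, 0] + dy[:, 1])
        assert total_rate == pytest.approx(0.0, abs=1e-12)


class TestMixing:
    def test_equal_concentrations_unchanged(self):
        cyc = make_cycle(n=3, V_n=0.8, V_C=2.0)
        c = np.array([0.1, 0.5, 0.9])
        st = EmbryoState(phase="interphase", U_nuc=c, U_cyt=c, W_nuc=c,
                         W_cyt=c, Z_nuc=c, Z_cyt=c)
        mixed = mix_at_mitosis(st, cyc)
        assert np.allclose(mixed.U_cyt, c)

    def test_equal_volumes_average(self):
        cyc = make_cycle(n=1, V_n=1.3, V_C=1.3)
        st = EmbryoState(phase="interphase",
                         U_nuc=np.array([2.0]), U_cyt=np.array([0.0]),
                         W_nuc=np.zeros(1), W_cyt=np.zeros(1),
                         Z_nuc=np.zeros(1), Z_cyt=np.zeros(1))
        assert mix_at_mitosis(st, cyc).U_cyt[0] == pytest.approx(1.0)

    def test_mass_audit_exact(self):
        rng = np.random.default_rng(1)
        cyc = make_cycle(n=7, V_n=0.37, V_C=1.91)
        fields = {k: rng.uniform(0, 2, 7)
                  for k in ("U_nuc", "U_cyt", "W_nuc", "W_cyt", "Z_nuc", "Z_cyt")}
        st = EmbryoState(phase="interphase", **fields)
        mixed = mix_at_mitosis(st, cyc)
        for nuc, cyt, out in (("U_nuc", "U_cyt", mixed.U_cyt),
                              ("W_nuc", "W_cyt", mixed.W_cyt),
                              ("Z_nuc", "Z_cyt", mixed.Z_cyt)):
            before = cyc.V_n_tilde * fields[nuc] + cyc.V_C_tilde * fields[cyt]
            after = (cyc.V_n_tilde + cyc.V_C_tilde) * out
            assert np.allclose(before, after, rtol=1e-15)


class TestRedistribution:
    def test_even_doubling_copies_parent_values(self):
        vals = np.array([0.2, 0.9, 0.1, 0.7])
        out = resample_piecewise_constant(vals, 8)
        assert np.array_equal(out, np.repeat(vals, 2))

    def test_odd_resampling_preserves_integral(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 3, 13)
        out = resample_piecewise_constant(vals, 25)
        assert np.mean(out) == pytest.approx(np.mean(vals), rel=1e-13)

    def test_extended_nuclei_inherit_cytoplasm(self):
        cyc = make_cycle(n=8)
        st = EmbryoState(phase="mitosis", U_cyt=np.full(4, 0.4),
                         W_cyt=np.full(4, 0.6), Z_cyt=np.full(4, 0.2))
        new = start_interphase(st, cyc, "extended")
        assert np.allclose(new.U_nuc, 0.4) and np.allclose(new.U_cyt, 0.4)
        assert np.allclose(new.Z_nuc, 0.2)

    def test_classic_nuclei_start_empty(self):
        cyc = make_cycle(n=8)
        st = EmbryoState(phase="mitosis", U_cyt=np.full(4, 0.4),
                         W_cyt=np.full(4, 0.6), Z_cyt=np.full(4, 0.2))
        new = start_interphase(st, cyc, "classic")
        assert np.allclose(new.U_nuc, 0.0) and np.allclose(new.W_nuc, 0.0)
        assert np.allclose(new.U_cyt, 0.4)


class TestInitialConditions:
    def test_matches_hand_solved_linear_system(self, schedule20):
        p = params(beta=0.0)  # the pre-Toll balance uses basal dissociation
        st = initial_conditions(schedule20, p, "extended")
        cyc = schedule20.cycle(10)
        An, Vn, VC = cyc.A_n_tilde, cyc.V_n_tilde, cyc.V_C_tilde
        # independent 2x2 solve: unknowns (Z_nuc, Z_cyt)
        A = np.array([
            [-An * p.xi_cact, An * p.zeta_cact],
            [An * p.xi_cact, -An * p.zeta_cact - p.alpha],
        ])
        b = np.array([-Vn * p.psi * p.beta0, -VC * p.psi * p.beta0 - 1.0])
        zn, zc = np.linalg.solve(A, b)
        assert st.Z_nuc[0] == pytest.approx(zn, rel=1e-12)
        assert st.Z_cyt[0] == pytest.approx(zc, rel=1e-12)
        # and the RHS vanishes for the Cact fields
        dy = interphase_rhs(st.pack(), p, cyc, cyc.dv_positions()
                            ).reshape(-1, 6)
        assert np.allclose(dy[:, 4], 0.0, atol=1e-12)
        assert np.allclose(dy[:, 5], 0.0, atol=1e-12)

    def test_complex_unity_free_dl_zero(self, schedule20):
        st = initial_conditions(schedule20, params(), "extended")
        assert np.all(st.W_nuc == 1.0) and np.all(st.W_cyt == 1.0)
        assert np.all(st.U_nuc == 0.0) and np.all(st.U_cyt == 0.0)

    def test_classic_nuclear_fields_zero(self, schedule20):
        st = initial_conditions(schedule20, params(), "classic")
        assert np.all(st.Z_nuc == 0) and np.all(st.W_nuc == 0)
        assert np.all(st.U_nuc == 0)
        p = params()
        cyc = schedule20.cycle(10)
        expect = (cyc.V_C_tilde * p.psi * p.beta0 + 1.0) / p.alpha
        assert st.Z_cyt[0] == pytest.approx(expect)

    def test_no_steady_state_without_degradation(self, schedule20):
        with pytest.raises(ValueError):
            initial_conditions(schedule20, params(alpha=0.0), "extended")


class TestSimulate:
    def test_no_toll_keeps_solution_uniform(self, schedule20):
        traj = simulate(params(beta=0.0), schedule20)
        for b in traj.blocks:
            spread = np.ptp(b.states, axis=1)  # over compartments
            assert spread.max() < 1e-7

    def test_nonnegative_fields(self, traj20):
        for b in traj20.blocks:
            assert b.states.min() >= 0.0

    def test_ventral_sawtooth(self, traj20):
        # ventral-most nuclear total dl rises within each interphase and
        # drops across each mitosis
        prev_end = None
        for cid in (11, 12, 13, 14):
            b = traj20.block_for_cycle(cid)
            v = b.states[:, 0, 0] + b.states[:, 0, 2]
            assert v[-1] > v[0]
            if prev_end is not None:
                assert v[0] < prev_end
            prev_end = v[-1]

    def test_dorsal_decline_extended_vs_classic(self, schedule20, traj20):
        b = traj20.block_for_cycle(14)
        dorsal = b.states[:, -1, 0] + b.states[:, -1, 2]
        assert dorsal[-1] < dorsal[0]  # extended: declines
        classic = simulate(DEFAULT_TRUE_PARAMS, schedule20, variant="classic")
        bc = classic.block_for_cycle(14)
        dorsal_c = bc.states[:, -1, 0] + bc.states[:, -1, 2]
        assert np.all(np.diff(dorsal_c) >= -1e-9)  # classic: cannot decline

    def test_dorsal_recovery_at_cycle_start(self, traj20):
        # dorsal signal recovers at each interphase onset after declining
        for cid in (12, 13, 14):
            prev = traj20.block_for_cycle(cid - 1)
            cur = traj20.block_for_cycle(cid)
            end_prev = prev.states[-1, -1, 0] + prev.states[-1, -1, 2]
            start_cur = cur.states[0, -1, 0] + cur.states[0, -1, 2]
            assert start_cur > end_prev

    def test_mass_conservation_small(self, traj20):
        masses = _dl_masses(traj20)
        assert np.ptp(masses) / masses[0] < 1e-6

    def test_state_dimensions_follow_schedule(self, traj20, schedule20):
        for b in traj20.blocks:
            assert b.states.shape[1] == schedule20.cycle(b.cycle_id).n_nuclei
        times = np.concatenate([b.times for b in traj20.blocks])
        assert np.all(np.diff(times) >= 0)

    def test_unknown_variant_rejected(self, schedule20):
        with pytest.raises(ValueError):
            simulate(params(), schedule20, variant="bogus")


class TestTwoCompartmentBindingOracle:
    def test_equilibrium_constant_reached(self):
        # no transport, no degradation/production, no Toll: pure binding
        # equilibrium U*Z/W = beta0/gamma in each compartment independently
        p = params(**ZERO_RATES, alpha=0.0, beta=0.0, beta0=0.4, gamma=1.3)
        cyc = make_cycle(n=2, V_C=1.7)
        z = cyc.dv_positions()
        y0 = np.array([
            0.0, 0.8, 0.0, 0.5, 0.0, 0.9,   # compartment 0
            0.0, 0.1, 0.0, 1.2, 0.0, 0.3,   # compartment 1
        ])
        sol = odeint(
            lambda t, y: interphase_rhs(y, p, cyc, z, cact_production=0.0),
            y0, [0.0, 2000.0], tfirst=True, rtol=1e-10, atol=1e-12,
        )
        m = sol[-1].reshape(2, 6)
        for h in range(2):
            U, W, Z = m[h, 1], m[h, 3], m[h, 5]
            assert U * Z / W == pytest.approx(p.beta0 / p.gamma, rel=1e-6)
        # conserved totals: dl and (scaled) Cact
        for h in range(2):
            dl0 = y0.reshape(2, 6)[h, 1] + y0.reshape(2, 6)[h, 3]
            assert m[h, 1] + m[h, 3] == pytest.approx(dl0, rel=1e-8)


def _dl_masses(traj):
    masses = []
    for b in traj.blocks:
        for i in range(len(b.times)):
            m = b.states[i]
            if b.phase == "interphase":
                masses.append(np.sum(
                    b.cyc.V_n_tilde * (m[:, 0] + m[:, 2])
                    + b.cyc.V_C_tilde * (m[:, 1] + m[:, 3])
                ))
            else:
                masses.append(np.sum(b.cyc.prism_volume_tilde * (m[:, 0] + m[:, 1])))
    return np.asarray(masses)


class TestParameterContainer:
    def test_roundtrip_array_json(self):
        p = params()
        assert ModelParameters.from_array(p.as_array()) == p
        assert ModelParameters.from_json(p.to_json()) == p

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            params(gamma=-1.0)
        with pytest.raises(ValueError):
            params(phi_prime=0.0)
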