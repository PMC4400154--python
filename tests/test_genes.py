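import numpy as np
import pytest
from scipy.integrate import quad

from dlcact.genes import (
    GENE_PARAM_NAMES,
    GeneParameters,
    boundary_position,
    boundary_width,
    dl_input_from_trajectory,
    effective_dl,
    production_rate,
    sensitivity_scan,
    simulate_expression,
)
from dlcact.synthetic import GENES


def gp(**kw):
    base = dict(
        theta_dl={"sna": 0.5, "vnd": 0.2, "sog": 0.05, "zen": 0.02},
        tau={"sna": 3.0, "vnd": 3.0, "sog": 3.0, "zen": 3.0},
        theta_sna={"vnd": 0.5, "sog": 0.5},
        eta=0.2,
        n_H=100.0,
    )
    base.update(kw)
    return GeneParameters(**base)


class TestEffectiveDl:
    def test_noise_free_is_identity(self):
        u = np.linspace(0, 2, 7)
        assert np.array_equal(effective_dl(u, 0.0, np.random.default_rng(0)), u)

    def test_zero_input_stays_zero(self):
        out = effective_dl(np.zeros(1000), 0.9, np.random.default_rng(1))
        assert np.all(out == 0.0)

    def test_mean_matches_quadrature_oracle(self):
        # E[max(0, 1 + 0.5 N)] by numeric integration of the normal density
        eta, u = 0.5, 1.0
        phi = lambda x: np.exp(-x * x / 2) / np.sqrt(2 * np.pi)
        expect, _ = quad(lambda x: max(0.0, u + eta * x * u) * phi(x), -10, 10)
        rng = np.random.default_rng(2)
        draws = effective_dl(np.full(200_000, u), eta, rng)
        assert draws.mean() == pytest.approx(expect, rel=2e-3)

    def test_clipped_at_zero(self):
        draws = effective_dl(np.full(10_000, 0.1), 1.0, np.random.default_rng(3))
        assert draws.min() == 0.0  # some draws dip below zero and are clipped


class TestProductionRate:
    def test_hill_midpoint(self):
        g = gp()
        assert production_rate("sna", 0.5, None, g) == pytest.approx(0.5)
        assert production_rate("zen", 0.02, None, g) == pytest.approx(0.5)

    def test_hard_threshold_sharpness(self):
        g = gp()
        val = production_rate("sna", 0.5 * 1.1, None, g)
        assert val == pytest.approx(1.0 / (1.0 + 1.1**-100), rel=1e-9)

    def test_sna_represses_vnd_regardless_of_dl(self):
        g = gp()
        assert production_rate("vnd", 2.0, 50.0, g) < 1e-6
        assert production_rate("vnd", 2.0, 0.0, g) > 0.999

    def test_zen_repressed_by_dl(self):
        g = gp()
        assert production_rate("zen", 1.0, None, g) < 1e-6
        assert production_rate("zen", 0.0, None, g) == pytest.approx(1.0)

    def test_zero_threshold_limit_convention(self):
        g = gp(theta_dl={"sna": 0.0, "vnd": 0.2, "sog": 0.05, "zen": 0.0})
        assert production_rate("sna", 0.0, None, g) == 0.0
        assert production_rate("zen", 0.0, None, g) == 1.0


def constant_input(u, n=10, nt=40):
    times = np.arange(float(nt))
    return times, np.full((n, nt), u)


class TestSimulateExpression:
    def test_saturating_production_closed_form(self):
        # f = 1 throughout: mRNA(t) = 1 - exp(-t/tau) on the minute grid
        g = gp(eta=0.0)
        times, mat = constant_input(2.0)  # far above every activation threshold
        prof = simulate_expression(times, mat, g, rng=0, replicate_count=1)
        sna = prof.mrna[0, :, 0]
        assert np.allclose(sna, 1.0 - np.exp(-times / 3.0), atol=1e-12)

    def test_mitosis_gap_decays_without_production(self):
        g = gp(eta=0.0)
        times = np.array([0.0, 1.0, 2.0, 7.0])  # 5-minute mitosis gap
        mat = np.full((3, 4), 2.0)
        prof = simulate_expression(times, mat, g, rng=0, replicate_count=1)
        sna = prof.mrna[0, :, 0]
        assert sna[3] == pytest.approx(sna[2] * np.exp(-5.0 / 3.0), rel=1e-12)

    def test_mrna_bounded_zero_one(self, traj20):
        times, mat = dl_input_from_trajectory(traj20, "free")
        prof = simulate_expression(times, mat, gp(eta=0.5), rng=1,
                                   replicate_count=2)
        assert prof.mrna.min() >= 0.0 and prof.mrna.max() <= 1.0 + 1e-12

    def test_noise_free_boundaries_sit_at_threshold_crossings(self):
        # static monotone gradient: each boundary lands within one
        # internuclear distance of where the gradient crosses the threshold
        n, nt = 50, 120
        z = (np.arange(n) + 0.5) / n
        grad = np.exp(-z**2 / (2 * 0.15**2))
        times = np.arange(float(nt))
        mat = np.tile(grad[:, None], (1, nt))
        g = gp(eta=0.0,
               theta_dl={"sna": 0.4, "vnd": 0.09, "sog": 0.004, "zen": 0.002},
               theta_sna={"vnd": 0.5, "sog": 0.5})
        prof = simulate_expression(times, mat, g, rng=0, replicate_count=1)
        for gene in ("sna", "vnd", "sog"):
            theta = g.theta_dl[gene]
            z_cross = np.sqrt(-2 * 0.15**2 * np.log(theta))
            b = boundary_position(prof.final_for(gene), z, gene)
            assert b == pytest.approx(z_cross, abs=1.0 / n)

    def test_replicate_averaging_shrinks_boundary_variance(self):
        n, nt = 50, 60
        z = (np.arange(n) + 0.5) / n
        grad = np.exp(-z**2 / (2 * 0.15**2))
        times = np.arange(float(nt))
        mat = np.tile(grad[:, None], (1, nt))
        g = gp(eta=0.4, theta_dl={"sna": 0.4, "vnd": 0.09, "sog": 0.02,
                                  "zen": 0.002})

        def boundary_samples(reps, seeds):
            out = []
            for s in seeds:
                prof = simulate_expression(times, mat, g, rng=s,
                                           replicate_count=reps)
                out.append(boundary_position(prof.final_for("sog"), z, "sog"))
            return np.var(out)

        v1 = boundary_samples(1, range(40))
        v10 = boundary_samples(10, range(40, 80))
        assert v10 < v1 / 3.0  # ~10x in expectation; allow stochastic slack


class TestBoundaryPosition:
    def test_ideal_step_border(self):
        # step on through nucleus 10: the on/off edge between nucleus
        # centers 0.21 and 0.23 interpolates to 0.22
        prof = np.where(np.arange(50) <= 10, 1.0, 0.0)
        assert boundary_position(prof, gene="sna") == pytest.approx(0.22, abs=1e-9)

    def test_constant_profile_has_no_domain(self):
        assert boundary_position(np.full(30, 0.7)) is None
        assert boundary_position(np.zeros(30)) is None

    def test_zen_measured_from_dorsal_side(self):
        z = (np.arange(50) + 0.5) / 50
        prof = np.where(z > 0.6, 1.0, 0.0)
        assert boundary_position(prof, z, "zen") == pytest.approx(0.6, abs=0.011)

    def test_band_reports_dorsal_edge(self):
        z = (np.arange(50) + 0.5) / 50
        prof = ((z > 0.2) & (z < 0.33)).astype(float)
        assert boundary_position(prof, z, "vnd") == pytest.approx(0.33, abs=0.011)

    def test_width_of_step_is_subnuclear(self):
        prof = np.where(np.arange(50) <= 10, 1.0, 0.0)
        assert boundary_width(prof, gene="sna") < 1.0 / 50


class TestSensitivity:
    def test_zero_delta_zero_discrepancy(self, traj20):
        times, mat = dl_input_from_trajectory(traj20, "free")
        g = gp(eta=0.2)
        out = sensitivity_scan(g, times, mat, params_to_vary=["theta_dl_sna"],
                               delta=0.0, replicate_count=2, seed=0)
        assert out["theta_dl_sna"]["plus"]["mean_abs_diff"] == pytest.approx(0.0)

    def test_scan_covers_requested_parameters(self, traj20):
        times, mat = dl_input_from_trajectory(traj20, "free")
        out = sensitivity_scan(gp(), times, mat,
                               params_to_vary=["theta_dl_sog", "eta"],
                               replicate_count=1, seed=0)
        assert set(out) == {"theta_dl_sog", "eta"}
        assert set(out["eta"]) == {"minus", "plus"}


class TestGeneParameters:
    def test_array_roundtrip(self):
        g = gp()
        g2 = GeneParameters.from_array(g.as_array(), eta=g.eta, n_H=g.n_H)
        assert g2 == g

    def test_validation(self):
        with pytest.raises(ValueError):
            gp(eta=1.5)
        with pytest.raises(ValueError):
            gp(tau={"sna": 0.0, "vnd": 3.0, "sog": 3.0, "zen": 3.0})
        assert len(GENE_PARAM_NAMES) == 10
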