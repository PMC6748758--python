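"""Benchmark simulators: ground truth, noise regimes, dynamics checks."""

import numpy as np
import pytest

from usdl.data import TimeSeriesCollection
from usdl.simulators import (GroundTruth, INTERVENTION_SCHEDULES,
                             PROTEIN_RATES, _protein_rhs_factory,
                             lorenz96_ground_truth, ou_stationary_covariance,
                             protein_basal_state,
                             protein_deterministic_trajectory,
                             protein_ground_truth, simulate_lorenz96,
                             simulate_ou, simulate_protein_network)


class TestProteinNetwork:
    def test_noise_free_samples_lie_on_deterministic_trajectory(self):
        ds, truth = simulate_protein_network(
            seed=0, measurement_sigma=0.0, heterogeneity=0.0, cells_per_time=1)
        times = np.array(truth.config["sample_times"])
        for iv in ("none", "P2"):
            det = protein_deterministic_trajectory(times, iv)
            for j, var in enumerate(["P1", "P2", "P3"]):
                t, y = ds.samples(f"exp_{iv}", var)
                assert np.max(np.abs(y - det[:, j])) < 1e-6

    def test_inhibited_species_stays_at_baseline(self):
        ds, _ = simulate_protein_network(seed=1, noise="low")
        t, y = ds.samples("exp_P2", "P2")
        # activity is baseline-referenced: the clamped species scatters
        # around zero with measurement + basal-heterogeneity noise only,
        # far below the ~2-unit stimulus excursions of active species
        assert abs(np.mean(y)) < 0.15
        assert np.std(y) < 0.6

    def test_high_noise_variance_is_about_four_times_low(self):
        # the high-uncertainty regime doubles every stochastic std dev
        n = 1000
        tpt = np.array([30.0])
        ds_lo, _ = simulate_protein_network(
            seed=3, noise="low", sample_times=tpt, cells_per_time=n,
            interventions=("none",))
        ds_hi, _ = simulate_protein_network(
            seed=3, noise="high", sample_times=tpt, cells_per_time=n,
            interventions=("none",))
        ratios = []
        for var in ["P1", "P2", "P3"]:
            lo = np.var(ds_lo.samples("exp_none", var)[1])
            hi = np.var(ds_hi.samples("exp_none", var)[1])
            ratios.append(hi / lo)
        assert 3.0 < np.mean(ratios) < 5.0

    def test_invalid_intervention_rejected(self):
        with pytest.raises(ValueError, match="unknown intervention"):
            simulate_protein_network(seed=0, interventions=("none", "P9"))

    def test_reproducible_from_seed(self):
        a, _ = simulate_protein_network(seed=5, cells_per_time=3)
        b, _ = simulate_protein_network(seed=5, cells_per_time=3)
        assert np.array_equal(a.data["value"], b.data["value"])

    def test_ground_truth_edges_match_sign_pattern(self):
        truth = protein_ground_truth()
        es = truth.edge_set()
        assert es.support() == {("P1", "P2"), ("P2", "P3"), ("P3", "P1")}
        assert es.edges[("P3", "P1")] < 0 < es.edges[("P1", "P2")]

    def test_sequestered_mass_is_conserved_without_degradation(self):
        # with production and degradation of P1 and C switched off, the
        # P1 + C moiety is conserved by the binding/release pair
        rates = dict(PROTEIN_RATES, d1=0.0, dc=0.0)
        r = {k: np.array([v]) for k, v in rates.items()}
        r["k0"] = np.array([0.0])
        rhs = _protein_rhs_factory(r, np.zeros((1, 3), dtype=bool))
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.uniform(0.1, 5.0, 4)
            d = rhs(0.0, s).reshape(4)
            assert d[0] + d[3] == pytest.approx(0.0, abs=1e-12)

    def test_basal_state_is_an_equilibrium(self):
        basal, k0 = protein_basal_state()
        r = {k: np.array([v]) for k, v in PROTEIN_RATES.items()}
        r["k0"] = np.array([k0])
        rhs = _protein_rhs_factory(r, np.zeros((1, 3), dtype=bool))
        assert np.max(np.abs(rhs(0.0, basal.copy()))) < 1e-12


class TestOrnsteinUhlenbeck:
    def test_drift_rows_have_bounded_out_degree(self):
        _, truth = simulate_ou(seed=2, N=20, n_paths=1, n_record=11)
        A = -truth.A
        off = A - np.diag(np.diag(A))
        assert np.all((np.abs(off) > 0).sum(axis=1) <= 3)
        assert np.all((np.abs(off) > 0).sum(axis=1) >= 1)

    def test_noiseless_transient_decays_monotonically(self):
        coll, _ = simulate_ou(seed=3, N=6, sigma=0.0, regime="transient",
                              n_paths=2, T=5.0, n_record=201)
        norms = np.linalg.norm(coll.paths, axis=2)
        assert np.all(np.diff(norms, axis=1) < 0)

    def test_stationary_covariance_solves_lyapunov_equation(self):
        coll, truth = simulate_ou(seed=4, N=6, sigma=0.5, regime="stationary",
                                  n_paths=30, T=30.0, n_record=1501)
        A = -truth.A
        sigma = truth.config["sigma"]
        X = coll.paths.reshape(-1, 6)
        S_emp = X.T @ X / X.shape[0]
        resid = A @ S_emp + S_emp @ A.T - sigma ** 2 * np.eye(6)
        assert np.linalg.norm(resid) < 0.2 * np.linalg.norm(
            sigma ** 2 * np.eye(6))
        S_true = ou_stationary_covariance(A, sigma)
        rel = np.linalg.norm(S_emp - S_true) / np.linalg.norm(S_true)
        assert rel < 0.2

    def test_reproducible_from_seed(self):
        a, _ = simulate_ou(seed=9, N=5, n_paths=2, T=1.0, n_record=51)
        b, _ = simulate_ou(seed=9, N=5, n_paths=2, T=1.0, n_record=51)
        assert np.array_equal(a.paths, b.paths)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_ou(seed=0, N=1)
        with pytest.raises(ValueError):
            simulate_ou(seed=0, regime="chaotic")


class TestLorenz96:
    def test_forcing_fixed_point_stays_constant(self):
        coll, _ = simulate_lorenz96(seed=0, N=5, n_paths=1, T=2.0,
                                    n_record=51, burn=0.0, x0_spread=0.0)
        assert np.max(np.abs(coll.paths - 8.0)) < 1e-6

    def test_energy_identity_along_trajectory(self):
        # d/dt sum x_k^2 = 2 sum x_k (F - x_k) for the cyclic system
        coll, truth = simulate_lorenz96(seed=1, N=6, n_paths=1, T=2.0,
                                        n_record=2001, rtol=1e-10)
        x = coll.paths[0]
        t = coll.times
        F = truth.forcing["x1"]
        energy = np.sum(x ** 2, axis=1)
        rhs = 2 * np.sum(x * (F - x), axis=1)
        lhs = energy[-1] - energy[0]
        assert lhs == pytest.approx(np.trapezoid(rhs, t), abs=1e-4 * abs(lhs))

    def test_ground_truth_row_support(self):
        truth = lorenz96_ground_truth(5, 8.0)
        for k in range(5):
            nz = np.flatnonzero(truth.A[k])
            assert nz.size == 3  # one linear, two quadratic atoms
        assert truth.forcing == {f"x{i+1}": 8.0 for i in range(5)}
        # quadratic atoms carry one +1 and one -1, linear atom is -1
        row = truth.A[0]
        assert sorted(row[np.flatnonzero(row)]) == [-1.0, -1.0, 1.0]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_lorenz96(seed=0, N=3)


def test_ground_truth_json_roundtrip(tmp_path):
    truth = protein_ground_truth()
    truth.to_json(tmp_path / "t.json")
    back = GroundTruth.from_json(tmp_path / "t.json")
    assert back.variables == truth.variables
    assert np.allclose(back.A, truth.A)
    assert back.edge_set().support() == truth.edge_set().support()


def test_noise_free_ou_satisfies_weak_form_with_true_drift():
    # sigma = 0 reduces the SDE to a linear ODE: the weak system is solved
    # by the generating coefficients up to Euler-step and quadrature error
    from usdl.dictionaries import make_linear_dictionary
    from usdl.weak_form import assemble
    coll, truth = simulate_ou(seed=5, N=5, sigma=0.0, regime="transient",
                              n_paths=3, T=5.0, n_record=2001)
    ws = assemble({p: (coll.times, coll.paths[p]) for p in range(3)},
                  coll.variables, make_linear_dictionary(5), "fourier:10")
    for i, v in enumerate(coll.variables):
        resid = ws.response_for(v) - ws.design_for(v) @ truth.A[i]
        assert np.linalg.norm(resid) < 1e-2 * np.linalg.norm(
            ws.response_for(v))
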