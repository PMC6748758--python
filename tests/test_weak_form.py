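"""Quadrature, weak-form projections, and system assembly."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from usdl.dictionaries import make_linear_dictionary
from usdl.test_functions import (make_bspline_family, make_fourier_family,
                                 make_peaky_fourier_family)
from usdl.weak_form import (WeakSystem, assemble, project_derivative,
                            project_dictionary, quadrature)


class TestQuadrature:
    def test_trapezoid_exact_for_linear(self):
        g = np.linspace(0, 1, 11)
        assert quadrature(g, g, "trapezoid") == pytest.approx(0.5)

    def test_constant_integrates_to_grid_span(self):
        g = np.array([0.0, 0.3, 1.1, 2.0, 5.0])
        assert quadrature(np.ones_like(g), g) == pytest.approx(5.0)

    def test_simpson_exact_for_cubic(self):
        g = np.linspace(0, 2, 101)
        assert quadrature(g ** 3, g, "simpson") == pytest.approx(4.0, abs=1e-10)

    def test_simpson_trailing_odd_interval_falls_back(self):
        g = np.linspace(0, 1, 10)  # 9 intervals: odd
        val = quadrature(g ** 2, g, "simpson")
        assert val == pytest.approx(1 / 3, abs=1e-3)

    def test_simpson_uneven_grid_falls_back_to_trapezoid(self):
        g = np.array([0.0, 0.1, 0.5, 1.0])
        assert quadrature(g, g, "simpson") == pytest.approx(
            quadrature(g, g, "trapezoid"))

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            quadrature([1.0, 2.0], [1.0, 0.5])
        with pytest.raises(ValueError):
            quadrature([1.0], [1.0])


class TestProjectDerivative:
    def test_constant_test_function_gives_boundary_difference(self):
        g = np.linspace(0, 1, 51)
        fam = make_fourier_family(1.0, 0)
        z = project_derivative(g, g, fam)  # x(t) = t
        assert z[0] == pytest.approx(1.0)

    def test_full_period_orthogonality(self):
        g = np.linspace(0, 2 * np.pi, 4001)
        fam = make_fourier_family(2 * np.pi, 1)
        z = project_derivative(np.sin(g), g, fam)
        assert z[1] == pytest.approx(0.0, abs=1e-6)  # <cos, sin> = 0

    def test_parts_identity_matches_closed_form(self):
        # x = e^t, phi = t on [0,1]: <x', phi> = integral t e^t dt = 1
        g = np.linspace(0, 1, 2001)
        from usdl.test_functions import CustomFamily
        fam = CustomFamily(1.0, [lambda t: t], [lambda t: np.ones_like(t)])
        z = project_derivative(np.exp(g), g, fam)
        assert z[0] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("fam", [
        make_fourier_family(3.0, 6),
        make_peaky_fourier_family(3.0, 4, 10.0),
        make_bspline_family(3.0, 5, 3),
    ], ids=["fourier", "peaky", "bspline"])
    def test_parts_agrees_with_direct_derivative_quadrature(self, fam):
        g = np.linspace(0, 3, 4001)
        x = np.exp(-0.3 * g) * np.sin(2 * g) + 0.5 * g
        dx = np.exp(-0.3 * g) * (2 * np.cos(2 * g) - 0.3 * np.sin(2 * g)) + 0.5
        z_parts = project_derivative(x, g, fam, "simpson")
        z_direct = (fam.values(g) * dx) @ __import__(
            "usdl.weak_form", fromlist=["quadrature_weights"]
        ).quadrature_weights(g, "simpson")
        assert np.max(np.abs(z_parts - z_direct)) < 1e-6

    def test_domain_must_cover_trajectory(self):
        fam = make_fourier_family(1.0, 2)
        g = np.linspace(0, 2, 21)
        with pytest.raises(ValueError, match="cover"):
            project_derivative(g, g, fam)


class TestProjectDictionary:
    def test_constant_atom_constant_test_function(self):
        g = np.linspace(0, 1, 11)
        fam = make_fourier_family(1.0, 0)
        block = project_dictionary(np.ones((11, 1)), g, fam)
        assert block[0, 0] == pytest.approx(1.0)

    def test_orthogonality_of_sine_and_cosine(self):
        g = np.linspace(0, 2 * np.pi, 4001)
        fam = make_fourier_family(2 * np.pi, 1)
        block = project_dictionary(np.sin(g)[:, None], g, fam, "simpson")
        assert block[2, 0] == pytest.approx(0.0, abs=1e-8)  # <sin, cos>

    def test_refinement_oracle(self):
        rng = np.random.default_rng(0)
        coarse = np.linspace(0, 2, 801)
        fine = np.linspace(0, 2, 6401)
        fam = make_fourier_family(2.0, 5)
        f = lambda t: np.column_stack([np.sin(3 * t), t ** 2])
        b_coarse = project_dictionary(f(coarse), coarse, fam, "simpson")
        b_fine = project_dictionary(f(fine), fine, fam, "simpson")
        assert np.max(np.abs(b_coarse - b_fine)) < 1e-8

    def test_non_finite_values_rejected(self):
        g = np.linspace(0, 1, 5)
        fam = make_fourier_family(1.0, 1)
        vals = np.ones((5, 2))
        vals[3, 1] = np.inf
        with pytest.raises(ValueError):
            project_dictionary(vals, g, fam)


def _linear_system_data(A, x0, T=10.0, n=2001):
    t = np.linspace(0, T, n)
    sol = solve_ivp(lambda tt, x: A @ x, (0, T), x0, t_eval=t,
                    rtol=1e-11, atol=1e-13)
    return t, sol.y.T


TRUE_A = np.array([[-0.5, 0.3, 0.0], [0.0, -0.4, 0.2], [0.6, 0.0, -0.7]])


class TestAssemble:
    def test_shapes_single_experiment(self):
        t = np.linspace(0, 1, 101)
        states = np.column_stack([t, t ** 2, np.sin(t)])
        ws = assemble({"p": (t, states)}, ["x1", "x2", "x3"],
                      make_linear_dictionary(3), make_fourier_family(1.0, 2))
        assert ws.psi_blocks["p"].shape == (5, 3)
        assert ws.response_for("x1").shape == (5,)

    def test_replicated_experiments_leave_ls_solution_unchanged(self):
        t, states = _linear_system_data(TRUE_A, np.array([1.0, -2.0, 1.5]))
        d = make_linear_dictionary(3)
        one = assemble({"a": (t, states)}, ["x1", "x2", "x3"], d, "fourier:10")
        rep = assemble({k: (t, states) for k in "abc"}, ["x1", "x2", "x3"],
                       d, "fourier:10")
        for v in ["x1", "x2", "x3"]:
            s1 = np.linalg.lstsq(one.design_for(v), one.response_for(v),
                                 rcond=None)[0]
            s3 = np.linalg.lstsq(rep.design_for(v), rep.response_for(v),
                                 rcond=None)[0]
            assert np.allclose(s1, s3, atol=1e-10)

    def test_noiseless_linear_ode_satisfies_weak_equation(self):
        t, states = _linear_system_data(TRUE_A, np.array([1.0, -2.0, 1.5]))
        ws = assemble({"p": (t, states)}, ["x1", "x2", "x3"],
                      make_linear_dictionary(3), "fourier:20", rule="simpson")
        for i, v in enumerate(["x1", "x2", "x3"]):
            resid = ws.response_for(v) - ws.design_for(v) @ TRUE_A[i]
            assert np.linalg.norm(resid) < 1e-6

    def test_experiment_order_permutation_preserves_ls_solution(self):
        t, s1 = _linear_system_data(TRUE_A, np.array([1.0, -2.0, 1.5]))
        _, s2 = _linear_system_data(TRUE_A, np.array([0.5, 1.0, -1.0]))
        d = make_linear_dictionary(3)
        fwd = assemble({"a": (t, s1), "b": (t, s2)}, ["x1", "x2", "x3"],
                       d, "fourier:8")
        rev = assemble({"b": (t, s2), "a": (t, s1)}, ["x1", "x2", "x3"],
                       d, "fourier:8")
        for v in ["x1", "x2", "x3"]:
            a1 = np.linalg.lstsq(fwd.design_for(v), fwd.response_for(v),
                                 rcond=None)[0]
            a2 = np.linalg.lstsq(rev.design_for(v), rev.response_for(v),
                                 rcond=None)[0]
            assert np.allclose(a1, a2, atol=1e-10)

    def test_intervened_variable_rows_are_dropped_and_recorded(self):
        t = np.linspace(0, 1, 101)
        states = np.column_stack([t, np.cos(t)])
        ws = assemble({"a": (t, states), "b": (t, states)}, ["u", "v"],
                      make_linear_dictionary(2, ["u", "v"]),
                      make_fourier_family(1.0, 2),
                      interventions={"a": {"u"}})
        assert ws.experiments_for("u") == ["b"]
        assert ws.excluded["u"] == ["a"]
        assert ws.experiments_for("v") == ["a", "b"]

    def test_variable_intervened_everywhere_is_uninferable(self):
        t = np.linspace(0, 1, 51)
        states = np.column_stack([t, t ** 2])
        ws = assemble({"a": (t, states)}, ["u", "v"],
                      make_linear_dictionary(2, ["u", "v"]),
                      make_fourier_family(1.0, 1),
                      interventions={"a": {"v"}})
        assert ws.uninferable == ["v"]

    def test_known_contribution_is_subtracted(self):
        # dx/dt = -x + F: with F known, the weak system is solved by a = -1
        F = 2.0
        t = np.linspace(0, 5, 2001)
        x = (1.0 - F) * np.exp(-t) + F
        ws = assemble({"p": (t, x[:, None])}, ["x1"],
                      make_linear_dictionary(1), "fourier:6", rule="simpson",
                      known_contributions={"x1": lambda tt: np.full_like(tt, F)})
        a = np.linalg.lstsq(ws.design_for("x1"), ws.response_for("x1"),
                            rcond=None)[0]
        assert a[0] == pytest.approx(-1.0, abs=1e-6)

    def test_matrix_bundle_roundtrip(self, tmp_path):
        t = np.linspace(0, 1, 101)
        states = np.column_stack([np.sin(t), np.cos(t)])
        ws = assemble({"a": (t, states)}, ["u", "v"],
                      make_linear_dictionary(2, ["u", "v"]),
                      make_fourier_family(1.0, 3))
        ws.to_dir(tmp_path / "bundle")
        back = WeakSystem.from_dir(tmp_path / "bundle")
        assert back.variables == ws.variables
        assert np.allclose(back.psi_blocks["a"], ws.psi_blocks["a"])
        assert np.allclose(back.response_for("u"), ws.response_for("u"))
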