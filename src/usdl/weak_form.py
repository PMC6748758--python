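"""Weak-formulation projection: from trajectories to an atemporal system.

Multiplying the dynamics ``dx_n/dt = sum_q a_nq psi_q(x)`` by a test
function ``phi_m`` and integrating over ``[0, T]`` gives, per variable, the
linear system ``z_n = Psi a_n`` with

    z_nm   = <dx_n/dt, phi_m> = x_n(t) phi_m(t) |_0^T - <x_n, dphi_m/dt>,
    Psi_mq = <psi_q(x), phi_m>,

where integration by parts moves the derivative onto the (analytically
known) test function, so the data are never differentiated.  Multiple
experiments concatenate by stacking their ``(z, Psi)`` blocks row-wise.
The same identity holds pathwise for SDE trajectories; the diffusion term
then appears only in the residual ``e = z - Psi a``.

Interventions: when a variable is inhibited in an experiment, its own
equation carries no information in that experiment, so its rows are dropped
from ``z_n`` (the intervened trajectory still feeds the design matrix of
the other variables).  Known contributions to the dynamics (e.g. a constant
forcing) are projected and subtracted from ``z_n`` before solving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .dictionaries import Dictionary
from .test_functions import TestFunctionFamily, family_from_spec

__all__ = [
    "quadrature",
    "quadrature_weights",
    "project_derivative",
    "project_dictionary",
    "assemble",
    "WeakSystem",
]


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size < 2:
        raise ValueError("quadrature grid needs at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("quadrature grid must be strictly increasing")
    return grid


def quadrature_weights(grid: np.ndarray, rule: str = "trapezoid") -> np.ndarray:
    """Weights w with ``integral ~= w @ f(grid)`` for the given rule.

    ``trapezoid`` handles arbitrary strictly increasing grids.  ``simpson``
    is the composite rule on evenly spaced grids (exact for cubics), falls
    back to a trapezoid step on a trailing odd interval, and falls back to
    the trapezoid rule entirely on uneven grids.
    """
    grid = _check_grid(grid)
    d = np.diff(grid)
    if rule == "trapezoid":
        w = np.zeros_like(grid)
        w[:-1] += d / 2
        w[1:] += d / 2
        return w
    if rule == "simpson":
        h = d[0]
        if not np.allclose(d, h, rtol=1e-8, atol=1e-12):
            return quadrature_weights(grid, "trapezoid")
        n_int = grid.size - 1
        w = np.zeros_like(grid)
        n_simp = n_int if n_int % 2 == 0 else n_int - 1
        if n_simp >= 2:
            w[0:n_simp + 1:2] += 2 * h / 3
            w[1:n_simp:2] += 4 * h / 3
            w[0] -= h / 3
            w[n_simp] -= h / 3
        if n_simp != n_int:  # trailing odd interval
            w[-2] += h / 2
            w[-1] += h / 2
        return w
    raise ValueError(f"unknown quadrature rule {rule!r}")


def quadrature(values: np.ndarray, grid: np.ndarray, rule: str = "trapezoid") -> float:
    """Integrate sampled values over the grid span with the given rule."""
    values = np.asarray(values, dtype=float)
    w = quadrature_weights(grid, rule)
    if values.shape[-1] != w.size:
        raise ValueError("values and grid lengths differ")
    return float(values @ w) if values.ndim == 1 else values @ w


def _check_domain(grid: np.ndarray, family: TestFunctionFamily) -> None:
    lo, hi = family.domain
    tol = 1e-9 * max(1.0, hi)
    if grid[0] < lo - tol or grid[-1] > hi + tol:
        raise ValueError(
            f"family domain [{lo}, {hi}] does not cover trajectory span "
            f"[{grid[0]}, {grid[-1]}]")


def project_derivative(x: np.ndarray, grid: np.ndarray,
                       family: TestFunctionFamily,
                       rule: str = "trapezoid") -> np.ndarray:
    """M-vector ``z`` of ``<dx/dt, phi_m>`` via integration by parts.

    ``z_m = x(b) phi_m(b) - x(a) phi_m(a) - <x, dphi_m/dt>`` over the grid
    span ``[a, b]``; the data are never differentiated.
    """
    grid = _check_grid(grid)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != grid.size:
        raise ValueError("trajectory and grid lengths differ")
    _check_domain(grid, family)
    ends = family.values(np.array([grid[0], grid[-1]]))
    boundary = x[-1] * ends[:, 1] - x[0] * ends[:, 0]
    dphi = family.derivatives(grid)
    w = quadrature_weights(grid, rule)
    return boundary - dphi @ (w * x)


def project_dictionary(psi_values: np.ndarray, grid: np.ndarray,
                       family: TestFunctionFamily,
                       rule: str = "trapezoid") -> np.ndarray:
    """M x Q block with ``Psi_mq = <psi_q(x), phi_m>`` over the grid span."""
    grid = _check_grid(grid)
    psi_values = np.asarray(psi_values, dtype=float)
    if psi_values.ndim == 1:
        psi_values = psi_values[:, None]
    if psi_values.shape[0] != grid.size:
        raise ValueError("psi_values rows must match grid length")
    if not np.all(np.isfinite(psi_values)):
        raise ValueError("non-finite dictionary values")
    _check_domain(grid, family)
    phi = family.values(grid)
    w = quadrature_weights(grid, rule)
    return (phi * w) @ psi_values


@dataclass
class WeakSystem:
    """The assembled atemporal system, stacked across experiments.

    ``psi_blocks[p]`` is the M_p x Q design block of experiment ``p`` and
    ``z_blocks[(p, var)]`` the matching response block; a variable's rows
    exist only for experiments in which it was not intervened on.
    """

    variables: list[str]
    labels: list[str]
    experiments: list
    psi_blocks: dict
    z_blocks: dict
    excluded: dict[str, list]
    family_kind: str
    rule: str
    uninferable: list[str] = field(default_factory=list)

    def experiments_for(self, variable: str) -> list:
        return [p for p in self.experiments if (p, variable) in self.z_blocks]

    def design_for(self, variable: str) -> np.ndarray:
        exps = self.experiments_for(variable)
        if not exps:
            raise ValueError(f"variable {variable!r} has no usable experiments")
        return np.vstack([self.psi_blocks[p] for p in exps])

    def response_for(self, variable: str) -> np.ndarray:
        exps = self.experiments_for(variable)
        if not exps:
            raise ValueError(f"variable {variable!r} has no usable experiments")
        return np.concatenate([self.z_blocks[(p, variable)] for p in exps])

    def full_design(self) -> np.ndarray:
        """All experiments stacked (the matrix MIP is estimated from)."""
        return np.vstack([self.psi_blocks[p] for p in self.experiments])

    # ---- matrix-bundle export/import ----------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "variables": self.variables,
            "labels": self.labels,
            "experiments": [str(p) for p in self.experiments],
            "excluded": {v: [str(p) for p in ps] for v, ps in self.excluded.items()},
            "family_kind": self.family_kind,
            "rule": self.rule,
            "uninferable": self.uninferable,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        for p in self.experiments:
            np.savetxt(path / f"psi_{p}.csv", self.psi_blocks[p], delimiter=",")
            for v in self.variables:
                if (p, v) in self.z_blocks:
                    np.savetxt(path / f"z_{p}_{v}.csv",
                               self.z_blocks[(p, v)], delimiter=",")

    @classmethod
    def from_dir(cls, path) -> "WeakSystem":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        psi_blocks, z_blocks = {}, {}
        for p in meta["experiments"]:
            psi_blocks[p] = np.atleast_2d(
                np.loadtxt(path / f"psi_{p}.csv", delimiter=","))
            for v in meta["variables"]:
                f = path / f"z_{p}_{v}.csv"
                if f.exists():
                    z_blocks[(p, v)] = np.atleast_1d(
                        np.loadtxt(f, delimiter=","))
        return cls(meta["variables"], meta["labels"], meta["experiments"],
                   psi_blocks, z_blocks,
                   {v: ps for v, ps in meta["excluded"].items()},
                   meta["family_kind"], meta["rule"], meta["uninferable"])


def _resolve_family(family, T: float) -> TestFunctionFamily:
    if isinstance(family, TestFunctionFamily):
        return family
    if isinstance(family, str):
        return family_from_spec(family, T)
    if callable(family):
        return family(T)
    raise TypeError("family must be a TestFunctionFamily, spec string, or factory")


def assemble(experiments: Mapping, variables: Sequence[str],
             dictionary: Dictionary, family,
             interventions: Mapping | None = None,
             known_contributions: Mapping[str, Callable] | None = None,
             rule: str = "trapezoid") -> WeakSystem:
    """Stack per-experiment weak-form blocks into one system.

    Parameters
    ----------
    experiments : mapping
        experiment id -> ``(grid, states)`` with ``grid`` shape (n_t,) and
        ``states`` shape (n_t, N), columns ordered as ``variables``.
    variables : sequence of str
        State variable names (dictionary arity must equal their count).
    dictionary : Dictionary
        Candidate functions evaluated along each trajectory.
    family : TestFunctionFamily, spec string, or callable T -> family
        A fixed family must cover every experiment's span; a string or
        factory is instantiated per experiment with that experiment's
        record length.
    interventions : mapping, optional
        experiment id -> iterable of intervened variable names; those
        variables' own equations are excluded from that experiment.
    known_contributions : mapping, optional
        variable -> callable ``g(t)``; its projection is subtracted from
        ``z_n`` (prior knowledge / known forcing).
    rule : str
        Quadrature rule for all inner products.
    """
    variables = list(variables)
    if dictionary.arity != len(variables):
        raise ValueError(
            f"dictionary arity {dictionary.arity} != {len(variables)} variables")
    interventions = dict(interventions or {})
    known_contributions = dict(known_contributions or {})

    psi_blocks, z_blocks = {}, {}
    excluded: dict[str, list] = {v: [] for v in variables}
    exp_ids = list(experiments)
    fam_kind = None
    for p in exp_ids:
        grid, states = experiments[p]
        grid = _check_grid(grid)
        states = np.asarray(states, dtype=float)
        fam = _resolve_family(family, float(grid[-1]))
        fam_kind = fam.kind
        psi_vals = dictionary.evaluate(states)
        psi_blocks[p] = project_dictionary(psi_vals, grid, fam, rule)
        blocked = set(interventions.get(p, ()))
        w = quadrature_weights(grid, rule)
        phi = fam.values(grid)
        for j, var in enumerate(variables):
            if var in blocked:
                excluded[var].append(p)
                continue
            z = project_derivative(states[:, j], grid, fam, rule)
            if var in known_contributions:
                g = np.broadcast_to(
                    np.asarray(known_contributions[var](grid), dtype=float),
                    grid.shape)
                z = z - phi @ (w * g)
            z_blocks[(p, var)] = z

    uninferable = [v for v in variables
                   if not any((p, v) in z_blocks for p in exp_ids)]
    return WeakSystem(variables, list(dictionary.labels), exp_ids,
                      psi_blocks, z_blocks, excluded,
                      fam_kind or "unknown", rule, uninferable)
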