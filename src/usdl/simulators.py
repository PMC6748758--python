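"""Benchmark simulators with known ground-truth structure.

Three generators cover the main regimes the inference method targets:

* a three-species protein interaction network with cycles and a latent
  (unmeasured) complex, sampled destructively under inhibitor
  interventions — emulating mass-cytometry-style time-course data;
* a multidimensional Ornstein-Uhlenbeck process ``dx = -A x dt + sigma dB``
  whose drift is a directed graph Laplacian (plus a stabilizing diagonal
  shift), in a transient or a stationary regime;
* the cyclic Lorenz96 system, chaotic and quadratic, with its constant
  forcing treated as a known contribution.

Every simulator is reproducible from its seed and returns its generating
connectivity matrix as a :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import cholesky, solve_continuous_lyapunov

from .data import TimeCourseDataset, TimeSeriesCollection
from .evaluation import EdgeSet, edges_from_matrix

__all__ = [
    "GroundTruth",
    "simulate_protein_network",
    "simulate_ou",
    "simulate_lorenz96",
    "ou_stationary_covariance",
    "PROTEIN_RATES",
]


@dataclass
class GroundTruth:
    """Generating connectivity over a named dictionary, plus derived edges."""

    variables: list[str]
    labels: list[str]
    A: np.ndarray
    forcing: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def edge_set(self, include_diagonal: bool = False) -> EdgeSet:
        return edges_from_matrix(self.A, self.labels, self.variables,
                                 include_diagonal=include_diagonal)

    def to_json(self, path) -> None:
        payload = {
            "variables": self.variables,
            "labels": self.labels,
            "A": self.A.tolist(),
            "forcing": self.forcing,
            "config": self.config,
            "seed": self.seed,
            "edges": [
                {"source": s, "target": t, "coefficient": c,
                 "sign": int(np.sign(c))}
                for (s, t), c in self.edge_set().items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["variables"], payload["labels"],
                   np.asarray(payload["A"], dtype=float),
                   payload.get("forcing", {}), payload.get("config", {}),
                   payload.get("seed"))


# ---------------------------------------------------------------------------
# Protein interaction network (destructive time-course sampling)
# ---------------------------------------------------------------------------

#: Mass-action rate constants of the surrogate network (time unit: minutes).
#: P1 is produced at a basal rate (derived so the network rests at the
#: basal state below) and catalyzes P2; P2 catalyzes P3; P3 catalyzes the
#: sequestration of P1 into an unmeasured complex C (the latent
#: confounder), which slowly releases P1 back.  All species degrade
#: first-order.  Coarse signed graph: the cycle P1 -> P2 -> P3 -| P1.
PROTEIN_RATES = {
    "k1": 0.15,   # P1 -> P1 + P2
    "k2": 0.20,   # P2 -> P2 + P3
    "kb": 0.025,  # P1 + P3 -> C + P3 (P3-catalyzed sequestration)
    "ku": 0.01,   # C -> P1 (slow release)
    "d1": 0.05, "d2": 0.15, "d3": 0.20, "dc": 0.30,  # degradation
}

#: Basal (resting) P1 activity; the other basal levels and the production
#: rate follow from it at equilibrium.  Basal levels are high relative to
#: the stimulus so the Jacobian linearization of the kinetics is accurate.
_PROTEIN_P1_BASAL = 4.0

#: Activation stimulus applied at t = 0 on top of the basal state
#: (predominantly on P1; the cocktail perturbs the others too, which
#: excites every node independently of the cascade).
PROTEIN_STIMULUS = np.array([2.0, 1.0, 1.5, 0.0])

#: Relaxation timescales are kept at or above ~5 minutes so that the
#: 13-point sampling grid resolves every mode, and P2/P3 share similar
#: kinetics so that the observational experiment alone leaves them
#: entangled — the interventions are what disambiguate the cycle.

_PROTEIN_VARS = ["P1", "P2", "P3"]


def protein_basal_state(rates: dict[str, float] | None = None
                        ) -> tuple[np.ndarray, float]:
    """Resting state (P1, P2, P3, C) and the production rate sustaining it.

    The experiment is a stimulus-relaxation design: cells rest at this
    equilibrium, the activation at t = 0 displaces them, and they relax
    back.  Deviations from the basal state then follow the Jacobian of the
    mass-action kinetics, whose off-diagonal sign pattern is the coarse
    graph being inferred.
    """
    r = dict(PROTEIN_RATES, **(rates or {}))
    p1 = _PROTEIN_P1_BASAL
    p2 = r["k1"] * p1 / r["d2"]
    p3 = r["k2"] * p2 / r["d3"]
    c = r["kb"] * p1 * p3 / (r["ku"] + r["dc"])
    k0 = r["d1"] * p1 + r["kb"] * p1 * p3 - r["ku"] * c
    return np.array([p1, p2, p3, c]), k0

INTERVENTION_SCHEDULES = {
    "none": (), "P1": ("P1",), "P2": ("P2",), "P3": ("P3",),
    "combined": ("P1", "P3"),
}


def _protein_rhs_factory(rates: dict[str, np.ndarray], clamp: np.ndarray):
    """Vectorized mass-action right-hand side over a batch of cells.

    ``rates`` values and ``clamp`` (boolean mask over P1..P3, broadcast per
    cell) have shape (n_cells,); the state is flattened (n_cells * 4,).
    """
    k0, k1, k2 = rates["k0"], rates["k1"], rates["k2"]
    kb, ku = rates["kb"], rates["ku"]
    d1, d2, d3, dc = rates["d1"], rates["d2"], rates["d3"], rates["dc"]

    def rhs(t, y):
        s = y.reshape(-1, 4)
        p1, p2, p3, c = s[:, 0], s[:, 1], s[:, 2], s[:, 3]
        dp1 = k0 - d1 * p1 - kb * p1 * p3 + ku * c
        dp2 = k1 * p1 - d2 * p2
        dp3 = k2 * p2 - d3 * p3
        dc_ = kb * p1 * p3 - (ku + dc) * c
        out = np.column_stack([dp1, dp2, dp3, dc_])
        out[:, :3] *= ~clamp  # inhibited species are held at their baseline
        return out.ravel()

    return rhs


def protein_ground_truth(rates: dict[str, float] | None = None,
                         config: dict | None = None,
                         seed: int | None = None) -> GroundTruth:
    """Coarse signed linear model implied by the surrogate network.

    The Jacobian of the measured species at the basal state: the cycle
    P1 -> P2 -> P3 -| P1 off the diagonal (P1 up-regulates P2, P2
    up-regulates P3, P3 down-regulates P1 via the catalyzed
    sequestration), negative diagonals (degradation plus sequestration
    loss).  Support and signs are the scoring target.
    """
    r = dict(PROTEIN_RATES, **(rates or {}))
    basal, _ = protein_basal_state(r)
    A = np.array([
        [-r["d1"] - r["kb"] * basal[2], 0.0, -r["kb"] * basal[0]],
        [r["k1"], -r["d2"], 0.0],
        [0.0, r["k2"], -r["d3"]],
    ])
    return GroundTruth(_PROTEIN_VARS, _PROTEIN_VARS, A,
                       config=config or {}, seed=seed)


def simulate_protein_network(
    seed: int,
    interventions: tuple[str, ...] = ("none", "P1", "P2", "P3", "combined"),
    noise: str = "low",
    sample_times: np.ndarray | None = None,
    cells_per_time: int = 60,
    measurement_sigma: float = 0.05,
    heterogeneity: float = 0.05,
    rates: dict[str, float] | None = None,
) -> tuple[TimeCourseDataset, GroundTruth]:
    """Destructively sampled time-courses from the surrogate protein network.

    One experiment per entry of ``interventions`` (a key of
    ``INTERVENTION_SCHEDULES``).  Each experiment applies the activation
    stimulus at t = 0 to cells resting at their basal state and follows
    the relaxation over [0, 60] minutes.  For each sample time,
    ``cells_per_time`` fresh cells are drawn: rate constants and the
    stimulus are jittered log-normally by ``heterogeneity`` (each cell
    rests at its own equilibrium), the cell's ODE is integrated to the
    sample time, and the three measured species are recorded with additive
    Gaussian noise ``measurement_sigma``.  Values are reported relative to
    the population resting state (background-referenced, as after standard
    cytometry pre-processing), so an unstimulated measurement scatters
    around zero; cell-to-cell basal variability ends up as additional
    sampling noise.  The unmeasured complex C never appears in the output.
    ``noise="high"`` doubles both stochastic standard deviations.  An
    inhibited species is clamped to its basal activity from t = 0 (the
    stimulus does not reach it), so its reported activity stays at
    baseline zero up to noise.
    """
    bad = [iv for iv in interventions if iv not in INTERVENTION_SCHEDULES]
    if bad:
        raise ValueError(f"unknown intervention target(s) {bad}; "
                         f"choose from {sorted(INTERVENTION_SCHEDULES)}")
    if noise not in ("low", "high"):
        raise ValueError("noise regime must be 'low' or 'high'")
    scale = 2.0 if noise == "high" else 1.0
    sig_meas = scale * measurement_sigma
    het = scale * heterogeneity
    if sample_times is None:
        sample_times = np.linspace(0.0, 60.0, 13)
    sample_times = np.asarray(sample_times, dtype=float)
    base_rates = dict(PROTEIN_RATES, **(rates or {}))
    basal_pop, _ = protein_basal_state(base_rates)
    rng = np.random.default_rng(seed)

    records = []
    iv_rows = []
    for iv_name in interventions:
        clamped_vars = INTERVENTION_SCHEDULES[iv_name]
        exp_id = f"exp_{iv_name}"
        for v in clamped_vars:
            iv_rows.append({"experiment": exp_id, "variable": v,
                            "type": "inhibition"})
        n_cells = sample_times.size * cells_per_time
        cell_times = np.repeat(sample_times, cells_per_time)
        jit = {k: v * np.exp(het * rng.standard_normal(n_cells))
               for k, v in base_rates.items()}
        # per-cell basal equilibrium from the cell's own rates
        p1 = _PROTEIN_P1_BASAL * np.exp(het * rng.standard_normal(n_cells))
        p2 = jit["k1"] * p1 / jit["d2"]
        p3 = jit["k2"] * p2 / jit["d3"]
        cc = jit["kb"] * p1 * p3 / (jit["ku"] + jit["dc"])
        jit["k0"] = jit["d1"] * p1 + jit["kb"] * p1 * p3 - jit["ku"] * cc
        basal = np.column_stack([p1, p2, p3, cc])
        stim = PROTEIN_STIMULUS[None, :] * np.exp(
            het * rng.standard_normal((n_cells, 4)))
        clamp = np.zeros((n_cells, 3), dtype=bool)
        for v in clamped_vars:
            clamp[:, _PROTEIN_VARS.index(v)] = True
        x0 = basal.copy()
        x0[:, :3] += np.where(clamp, 0.0, stim[:, :3])
        rhs = _protein_rhs_factory(jit, clamp)
        t_end = float(sample_times.max())
        if t_end == 0.0:
            states = x0
        else:
            sol = solve_ivp(rhs, (0.0, t_end), x0.ravel(), method="RK45",
                            rtol=1e-8, atol=1e-10, dense_output=True)
            if not sol.success:  # pragma: no cover - defensive
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            states = np.empty_like(x0)
            for c, tc in enumerate(cell_times):
                states[c] = sol.sol(tc).reshape(-1, 4)[c]
        measured = (states[:, :3] - basal_pop[None, :3]
                    + sig_meas * rng.standard_normal((n_cells, 3)))
        for c, tc in enumerate(cell_times):
            for j, var in enumerate(_PROTEIN_VARS):
                records.append((exp_id, tc, var, measured[c, j]))

    data = pd.DataFrame(records, columns=["experiment", "time", "variable",
                                          "value"])
    iv_tab = pd.DataFrame(iv_rows, columns=["experiment", "variable", "type"])
    config = {
        "system": "protein", "interventions": list(interventions),
        "noise": noise, "cells_per_time": cells_per_time,
        "measurement_sigma": sig_meas, "heterogeneity": het,
        "sample_times": sample_times.tolist(), "rates": base_rates,
    }
    truth = protein_ground_truth(base_rates, config, seed)
    return TimeCourseDataset(data, iv_tab), truth


def protein_deterministic_trajectory(times: np.ndarray,
                                     intervention: str = "none",
                                     rates: dict[str, float] | None = None
                                     ) -> np.ndarray:
    """Noise-free, heterogeneity-free trajectory of the measured species,
    baseline-referenced like the simulated measurements (resting state = 0)."""
    times = np.asarray(times, dtype=float)
    r = dict(PROTEIN_RATES, **(rates or {}))
    basal, k0 = protein_basal_state(r)
    base = {k: np.array([v]) for k, v in r.items()}
    base["k0"] = np.array([k0])
    clamp = np.zeros((1, 3), dtype=bool)
    for v in INTERVENTION_SCHEDULES[intervention]:
        clamp[0, _PROTEIN_VARS.index(v)] = True
    x0 = basal.copy()
    x0[:3] += np.where(clamp[0], 0.0, PROTEIN_STIMULUS[:3])
    rhs = _protein_rhs_factory(base, clamp)
    sol = solve_ivp(rhs, (0.0, float(times.max())), x0,
                    t_eval=times, rtol=1e-10, atol=1e-12, dense_output=False)
    return sol.y.T[:, :3] - basal[None, :3]


# ---------------------------------------------------------------------------
# Multidimensional Ornstein-Uhlenbeck process
# ---------------------------------------------------------------------------

def _laplacian_drift(N: int, max_in_edges: int, eps: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Directed graph Laplacian drift with a stabilizing diagonal shift.

    Each variable is driven by 1..max_in_edges random others with unit
    weight: ``A_ij = -1`` on edges, ``A_ii = (row degree) + eps``.  The
    shift ``eps`` removes the Laplacian's zero eigenvalue so a stationary
    law exists.
    """
    A = np.zeros((N, N))
    for i in range(N):
        d = int(rng.integers(1, max_in_edges + 1))
        others = np.delete(np.arange(N), i)
        nbrs = rng.choice(others, size=d, replace=False)
        A[i, nbrs] = -1.0
        A[i, i] = d + eps
    return A


def ou_stationary_covariance(A: np.ndarray, sigma: float) -> np.ndarray:
    """Solve the Lyapunov equation A S + S A^T = sigma^2 I for the
    stationary covariance of ``dx = -A x dt + sigma dB``."""
    N = A.shape[0]
    return solve_continuous_lyapunov(-A, -sigma ** 2 * np.eye(N))


def simulate_ou(
    seed: int,
    N: int = 20,
    sigma: float = 0.5,
    regime: str = "transient",
    n_paths: int = 100,
    T: float = 10.0,
    max_out_degree: int = 3,
    eps: float = 0.5,
    dt: float | None = None,
    n_record: int = 1501,
    x0_scale: float = 3.0,
    A: np.ndarray | None = None,
) -> tuple[TimeSeriesCollection, GroundTruth]:
    """Euler-Maruyama sample paths of ``dx = -A x dt + sigma dB``.

    ``A`` defaults to a random graph-Laplacian drift (at most
    ``max_out_degree`` off-diagonal entries per row) plus ``eps`` on the
    diagonal.  ``regime="transient"`` starts far from equilibrium
    (components uniform on ``[-x0_scale, x0_scale]``) so the drift
    dominates; ``regime="stationary"`` starts from a draw of the stationary
    law (Lyapunov solve) so the diffusion dominates.  The integration step
    defaults to 1e-3 of the drift's fastest timescale; paths are recorded
    on an ``n_record``-point uniform grid.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if regime not in ("transient", "stationary"):
        raise ValueError("regime must be 'transient' or 'stationary'")
    rng = np.random.default_rng(seed)
    if A is None:
        A = _laplacian_drift(N, max_out_degree, eps, rng)
    A = np.asarray(A, dtype=float)
    evals = np.linalg.eigvals(A)
    if np.any(evals.real <= 0):  # pragma: no cover - construction prevents it
        raise RuntimeError("drift matrix is not stable")

    fastest = float(np.max(np.abs(np.diag(A))))
    if dt is None:
        dt = 1e-3 / fastest
    record_times = np.linspace(0.0, T, n_record)
    n_steps = int(np.ceil(T / dt))
    dt = T / n_steps  # exact landing on T

    if regime == "transient":
        x = rng.uniform(-x0_scale, x0_scale, size=(n_paths, N))
    else:
        S = ou_stationary_covariance(A, sigma)
        L = cholesky(S, lower=True)
        x = rng.standard_normal((n_paths, N)) @ L.T

    paths = np.empty((n_paths, n_record, N))
    paths[:, 0] = x
    M = np.eye(N) - dt * A
    sq = sigma * np.sqrt(dt)
    next_rec = 1
    t = 0.0
    for step in range(1, n_steps + 1):
        x = x @ M.T
        if sigma > 0:
            x += sq * rng.standard_normal((n_paths, N))
        t = step * dt
        while next_rec < n_record and record_times[next_rec] <= t + 1e-12:
            paths[:, next_rec] = x
            next_rec += 1
    variables = [f"x{i + 1}" for i in range(N)]
    config = {"system": "ou", "N": N, "sigma": sigma, "regime": regime,
              "n_paths": n_paths, "T": T, "dt": dt, "eps": eps,
              "max_out_degree": max_out_degree}
    truth = GroundTruth(variables, variables, -A, config=config, seed=seed)
    return TimeSeriesCollection(record_times, paths, variables), truth


# ---------------------------------------------------------------------------
# Lorenz96
# ---------------------------------------------------------------------------

def _lorenz96_rhs(t, x, F):
    return (np.roll(x, -1) - np.roll(x, 2)) * np.roll(x, 1) - x + F


def lorenz96_ground_truth(N: int, F: float,
                          config: dict | None = None,
                          seed: int | None = None) -> GroundTruth:
    """Cyclic Lorenz96 coefficients over the quadratic dictionary.

    Row k carries -1 on the linear atom x_k, +1 on the product
    x_{k-1} x_{k+1} and -1 on x_{k-2} x_{k-1} (indices mod N); the constant
    forcing F is a known contribution, not a dictionary atom.
    """
    from .dictionaries import make_quadratic_dictionary
    d = make_quadratic_dictionary(N)
    idx = {lab: j for j, lab in enumerate(d.labels)}

    def pair(i, j):
        i, j = sorted(((i % N) + 1, (j % N) + 1))
        return idx[f"x{i}*x{j}"]

    A = np.zeros((N, d.size))
    for k in range(N):
        A[k, idx[f"x{k + 1}"]] = -1.0
        A[k, pair(k - 1, k + 1)] = 1.0
        A[k, pair(k - 2, k - 1)] = -1.0
    variables = [f"x{i + 1}" for i in range(N)]
    return GroundTruth(variables, list(d.labels), A,
                       forcing={v: F for v in variables},
                       config=config or {}, seed=seed)


def simulate_lorenz96(
    seed: int,
    N: int = 5,
    F: float = 8.0,
    n_paths: int = 10,
    T: float = 5.0,
    n_record: int = 501,
    burn: float = 5.0,
    x0_spread: float = 0.5,
    rtol: float = 1e-8,
) -> tuple[TimeSeriesCollection, GroundTruth]:
    """Trajectories of the cyclic Lorenz96 system on its attractor.

    Each path starts from the forcing fixed point perturbed by Gaussian
    noise of scale ``x0_spread``, discards a ``burn`` period, then records
    ``n_record`` evenly spaced points over ``[0, T]``.
    """
    if N < 4:
        raise ValueError("Lorenz96 needs N >= 4 (cyclic indices degenerate)")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, T, n_record)
    paths = np.empty((n_paths, n_record, N))
    for p in range(n_paths):
        x0 = F + x0_spread * rng.standard_normal(N)
        sol = solve_ivp(_lorenz96_rhs, (0.0, burn + T), x0, args=(F,),
                        t_eval=burn + times, rtol=rtol, atol=1e-10)
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"Lorenz96 integration failed: {sol.message}")
        paths[p] = sol.y.T
    variables = [f"x{i + 1}" for i in range(N)]
    config = {"system": "lorenz96", "N": N, "F": F, "n_paths": n_paths,
              "T": T, "burn": burn, "n_record": n_record}
    truth = lorenz96_ground_truth(N, F, config, seed)
    return TimeSeriesCollection(times, paths, variables), truth
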