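"""End-to-end structure inference: the :class:`USDL` estimator.

The full procedure, per fit:

1. (time-course data only) reconstruct one smooth trajectory per variable
   per experiment by penalized-spline collocation;
2. project trajectories and dictionary evaluations onto the test functions
   (weak formulation) and stack experiments into ``z_n = Psi a_n``;
3. estimate the mutual incoherence of the stacked design;
4. solve each variable's sparse recovery problem with OMP;
5. evaluate the exact recovery coefficient at each estimated support.

The estimator exposes the learned coefficient matrix as ``coef_``, the
derived signed network as ``edges_``, and the recoverability metrics as
``mip_`` / ``erc_`` / ``diagnostics_``.  Hyperparameter selection by F1
score and stability selection over data subsamples are provided as
module-level helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .collocation import baseline_adjust, fit_experiment
from .data import TimeCourseDataset, TimeSeriesCollection
from .diagnostics import RecoveryDiagnostics, erc, lambda_min, mip
from .dictionaries import Dictionary, dictionary_from_spec
from .evaluation import EdgeSet, edges_from_matrix, precision_recall
from .ssr_omp import SparseSolution, solve_system
from .weak_form import WeakSystem, assemble

__all__ = ["USDL", "USDLResult", "run_usdl", "select_alpha",
           "stability_selection"]


@dataclass
class USDLResult:
    """Bundle of everything one fit produces."""

    A_hat: np.ndarray
    variables: list[str]
    labels: list[str]
    diagnostics: RecoveryDiagnostics
    edges: EdgeSet
    solutions: dict[str, SparseSolution]
    weak_system: WeakSystem


class USDL(BaseEstimator):
    """Unified sparse dynamics learning.

    Parameters
    ----------
    dictionary : str or Dictionary, default="linear"
        Candidate functions: ``"linear"``, ``"quadratic"``, or a prebuilt
        :class:`~usdl.dictionaries.Dictionary`.
    test_functions : str, family, or callable, default="fourier:20"
        Test-function family; a spec string (``"fourier:K"``,
        ``"peaky:K,kappa"``, ``"bspline:K,degree"``) or factory is
        instantiated per experiment with that experiment's record length.
    alpha : float, default=0.1
        OMP stopping parameter (sparser solutions for larger values).
    kmax : int or None
        Maximum support size per equation (default ``min(Q, 10)``).
    criterion : {"noise-floor", "relative"}
        OMP stopping criterion.
    mode : {"auto", "timeseries", "timecourse"}
        ``timecourse`` runs collocation first; ``auto`` chooses
        ``timecourse`` when some (experiment, variable) pair has repeated
        sample times (destructive sampling leaves replicates).
    rule : {"trapezoid", "simpson"}
        Quadrature rule for the weak-form inner products.
    n_eval_points : int, default=512
        Dense-grid size on which collocation trajectories are evaluated
        before projection.
    lam : float or "gcv", default="gcv"
        Collocation smoothing weight policy.
    spline_degree, n_interior_knots
        Collocation basis controls (see
        :class:`~usdl.collocation.PenalizedSplineSmoother`).
    adjust_baseline : bool, default=False
        Subtract each reconstructed trajectory's minimum (its no-activity
        baseline) before projection.
    known_contributions : mapping or None
        variable -> known forcing (a float or a callable of time) to be
        subtracted from that variable's response.

    Attributes
    ----------
    coef_ : (N, Q) ndarray — estimated connectivity matrix.
    mip_ : float — mutual incoherence of the stacked design.
    erc_ : dict — ERC at each variable's estimated support.
    edges_ : EdgeSet — signed off-diagonal network.
    diagnostics_ : RecoveryDiagnostics
    solutions_ : dict of per-variable SparseSolution.
    weak_system_ : WeakSystem
    """

    def __init__(self, dictionary="linear", test_functions="fourier:20",
                 alpha: float = 0.1, kmax: int | None = None,
                 criterion: str = "noise-floor", mode: str = "auto",
                 rule: str = "trapezoid", n_eval_points: int = 512,
                 lam="gcv", spline_degree: int = 3,
                 n_interior_knots: int | None = None,
                 adjust_baseline: bool = False,
                 known_contributions=None):
        self.dictionary = dictionary
        self.test_functions = test_functions
        self.alpha = alpha
        self.kmax = kmax
        self.criterion = criterion
        self.mode = mode
        self.rule = rule
        self.n_eval_points = n_eval_points
        self.lam = lam
        self.spline_degree = spline_degree
        self.n_interior_knots = n_interior_knots
        self.adjust_baseline = adjust_baseline
        self.known_contributions = known_contributions

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        ws = self.assemble_weak_system(X)
        self._solve(ws)
        return self

    def fit_weak_system(self, ws: WeakSystem):
        """Fit from an already-assembled weak system (hyperparameter sweeps)."""
        self._solve(ws)
        return self

    def predict_derivative(self, states: np.ndarray) -> np.ndarray:
        """dx/dt implied by the learned coefficients at given states."""
        check_is_fitted(self, "coef_")
        vals = self._dictionary_.evaluate(states)
        out = vals @ self.coef_.T
        for j, var in enumerate(self.variables_):
            if var in self._known_:
                out[:, j] += self._known_scalar_(var)
        return out

    # ------------------------------------------------------------------
    def assemble_weak_system(self, X) -> WeakSystem:
        experiments, variables, interventions = self._gather(X)
        if isinstance(self.dictionary, Dictionary):
            dictionary = self.dictionary
        else:
            dictionary = dictionary_from_spec(self.dictionary, len(variables),
                                              names=variables)
        self._dictionary_ = dictionary
        self._known_ = known = self._resolve_known()
        ws = assemble(experiments, variables, dictionary,
                      self.test_functions, interventions=interventions,
                      known_contributions=known, rule=self.rule)
        return ws

    def _resolve_known(self) -> dict:
        known = {}
        for var, g in (self.known_contributions or {}).items():
            if callable(g):
                known[var] = g
            else:
                known[var] = (lambda c: (lambda t: np.full_like(t, c)))(float(g))
        return known

    def _known_scalar_(self, var):
        g = self._known_[var]
        return g(np.zeros(1))[0]

    def _gather(self, X):
        """Normalize input to (experiments mapping, variables, interventions)."""
        if isinstance(X, TimeSeriesCollection):
            exps = {f"path{p + 1}": (X.times, X.paths[p])
                    for p in range(X.n_paths)}
            return exps, list(X.variables), {}
        if isinstance(X, Mapping):
            exps = {k: (np.asarray(t, float), np.asarray(s, float))
                    for k, (t, s) in X.items()}
            any_states = next(iter(exps.values()))[1]
            variables = [f"x{i + 1}" for i in range(any_states.shape[1])]
            return exps, variables, {}
        if not isinstance(X, TimeCourseDataset):
            raise TypeError(
                "X must be a TimeCourseDataset, TimeSeriesCollection, or a "
                "mapping of experiment -> (grid, states)")
        return self._gather_dataset(X)

    def _gather_dataset(self, ds: TimeCourseDataset):
        variables = ds.variables
        mode = self.mode
        if mode == "auto":
            has_replicates = (
                ds.data.duplicated(["experiment", "variable", "time"]).any())
            mode = "timecourse" if has_replicates else "timeseries"
        if mode not in ("timeseries", "timecourse"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.mode_ = mode
        interventions = {p: ds.intervened(p) for p in ds.experiments}
        exps = {}
        self.trajectories_ = {}
        if mode == "timeseries":
            for p in ds.experiments:
                tab = ds.experiment_table(p)
                pivot = tab.pivot_table(index="time", columns="variable",
                                        values="value")
                if pivot.isna().any().any():
                    missing = pivot.columns[pivot.isna().any()].tolist()
                    raise ValueError(
                        f"experiment {p!r}: variables {missing} not measured "
                        "on the shared grid (time-series mode)")
                grid = pivot.index.to_numpy(dtype=float)
                exps[p] = (grid, pivot[variables].to_numpy(dtype=float))
        else:
            for p in ds.experiments:
                trajs = fit_experiment(ds, p, degree=self.spline_degree,
                                       n_interior_knots=self.n_interior_knots,
                                       lam=self.lam)
                missing = [v for v in variables if v not in trajs]
                if missing:
                    raise ValueError(
                        f"experiment {p!r}: cannot reconstruct {missing} "
                        "(need >= 2 distinct sample times)")
                if self.adjust_baseline:
                    trajs = {v: baseline_adjust(tr) for v, tr in trajs.items()}
                self.trajectories_[p] = trajs
                lo = min(tr.domain[0] for tr in trajs.values())
                hi = max(tr.domain[1] for tr in trajs.values())
                grid = np.linspace(lo, hi, self.n_eval_points)
                states = np.column_stack([trajs[v](grid) for v in variables])
                # weak form works on [0, T]; shift the origin if needed
                exps[p] = (grid - lo, states)
        return exps, variables, interventions

    # ------------------------------------------------------------------
    def _solve(self, ws: WeakSystem) -> None:
        design = ws.full_design()
        try:
            self.mip_ = mip(design)
        except ValueError as exc:
            warnings.warn(f"MIP unavailable: {exc}", stacklevel=2)
            self.mip_ = float("nan")
        A_hat, solutions = solve_system(ws, alpha=self.alpha, kmax=self.kmax,
                                        criterion=self.criterion)
        erc_pv, lam_pv, res_pv, supports = {}, {}, {}, {}
        for var in ws.variables:
            sol = solutions[var]
            supports[var] = list(sol.support)
            res_pv[var] = sol.residual_norms[-1]
            if sol.support:
                Psi_n = ws.design_for(var)
                try:
                    erc_pv[var] = erc(Psi_n, sol.support)
                    lam_pv[var] = lambda_min(Psi_n, sol.support)
                except ValueError:
                    erc_pv[var] = None
                    lam_pv[var] = None
            else:
                erc_pv[var] = None
                lam_pv[var] = None
        self.weak_system_ = ws
        self.variables_ = list(ws.variables)
        self.labels_ = list(ws.labels)
        self.coef_ = A_hat
        self.solutions_ = solutions
        self.erc_ = erc_pv
        self.diagnostics_ = RecoveryDiagnostics(self.mip_, erc_pv, supports,
                                                lam_pv, res_pv)
        self.edges_ = edges_from_matrix(A_hat, ws.labels, ws.variables,
                                        include_diagonal=False)

    def result_(self) -> USDLResult:
        check_is_fitted(self, "coef_")
        return USDLResult(self.coef_.copy(), list(self.variables_),
                          list(self.labels_), self.diagnostics_, self.edges_,
                          self.solutions_, self.weak_system_)


def run_usdl(data, **params) -> USDLResult:
    """One-call pipeline: fit :class:`USDL` on data, return its outputs."""
    return USDL(**params).fit(data).result_()


def _truth_edges(truth, include_diagonal: bool) -> EdgeSet:
    if isinstance(truth, EdgeSet):
        return truth
    return truth.edge_set(include_diagonal=include_diagonal)


def select_alpha(data, truth, alpha_grid, include_diagonal: bool = False,
                 signed: bool = False, **params
                 ) -> tuple[float, pd.DataFrame]:
    """Pick the OMP stopping parameter that maximizes F1 against a truth.

    The weak system is assembled once and re-solved per grid value; ties
    resolve to the smallest alpha.  Returns the winner and the full score
    table (alpha, precision, recall, f1).
    """
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid must be nonempty")
    true_edges = _truth_edges(truth, include_diagonal)
    est = USDL(**params)
    ws = est.assemble_weak_system(data)
    rows = []
    best_alpha, best_f1 = None, -1.0
    for alpha in sorted(alpha_grid):
        est.set_params(alpha=alpha).fit_weak_system(ws)
        edges = edges_from_matrix(est.coef_, est.labels_, est.variables_,
                                  include_diagonal=include_diagonal)
        p, r, f1 = precision_recall(edges, true_edges, signed=signed)
        rows.append({"alpha": alpha, "precision": p, "recall": r, "f1": f1})
        if f1 > best_f1:
            best_alpha, best_f1 = alpha, f1
    return best_alpha, pd.DataFrame(rows)


def stability_selection(data, B: int = 100, fraction: float = 0.8,
                        threshold: float = 0.8, seed: int = 0,
                        include_diagonal: bool = False, **params
                        ) -> tuple[EdgeSet, pd.DataFrame]:
    """Consensus network over repeated inference on data subsamples.

    Each of the ``B`` repeats draws a random portion of the data — whole
    experiments when several are available, otherwise time points — reruns
    the full pipeline, and tallies edge frequencies; edges present in at
    least ``threshold`` of the repeats form the consensus network.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("subsample fraction must be in (0, 1]")
    if not 0 < threshold <= 1:
        raise ValueError("consensus threshold must be in (0, 1]")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    coef_sums: dict[tuple[str, str], float] = {}
    for _ in range(B):
        sub = _subsample(data, fraction, rng)
        res = run_usdl(sub, **params)
        edges = edges_from_matrix(res.A_hat, res.labels, res.variables,
                                  include_diagonal=include_diagonal)
        for (s, t), c in edges.items():
            counts[(s, t)] = counts.get((s, t), 0) + 1
            coef_sums[(s, t)] = coef_sums.get((s, t), 0.0) + c
    rows = [{"source": s, "target": t, "frequency": n / B,
             "mean_coefficient": coef_sums[(s, t)] / n}
            for (s, t), n in sorted(counts.items())]
    table = pd.DataFrame(rows, columns=["source", "target", "frequency",
                                        "mean_coefficient"])
    consensus = EdgeSet(includes_diagonal=include_diagonal)
    for row in rows:
        if row["frequency"] >= threshold:
            consensus.add(row["source"], row["target"],
                          row["mean_coefficient"])
    return consensus, table


def _subsample(data, fraction: float, rng: np.random.Generator):
    if isinstance(data, TimeSeriesCollection):
        P = data.n_paths
        if P > 1:
            k = max(1, int(round(fraction * P)))
            return data.subset_paths(rng.choice(P, size=k, replace=False))
        n_t = data.times.size
        k = max(2, int(round(fraction * n_t)))
        keep = np.sort(rng.choice(n_t, size=k, replace=False))
        return TimeSeriesCollection(data.times[keep], data.paths[:, keep],
                                    list(data.variables))
    if isinstance(data, TimeCourseDataset):
        exps = data.experiments
        if len(exps) > 1:
            k = max(1, int(round(fraction * len(exps))))
            pick = rng.choice(len(exps), size=k, replace=False)
            return data.subset_experiments([exps[i] for i in pick])
        exp = exps[0]
        times = np.unique(data.experiment_table(exp)["time"])
        k = max(2, int(round(fraction * times.size)))
        keep = np.sort(rng.choice(times.size, size=k, replace=False))
        return data.subset_times({exp: times[keep]})
    raise TypeError("stability selection needs a TimeCourseDataset or "
                    "TimeSeriesCollection")
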