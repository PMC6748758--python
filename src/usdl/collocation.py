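"""Collocation: reconstruct smooth trajectories from destructive samples.

Time-course measurements destroy the sampled object, so no single object
yields a trajectory.  Assuming all objects are drawn from one distribution,
a trajectory per variable is reconstructed by representing it as a weighted
sum of B-spline basis functions fitted by penalized least squares

    min_c  sum_i (y_i - sum_j c_j B_j(t_i))^2 + lambda * int (x''(t))^2 dt,

the integrated-squared-second-derivative roughness penalty standard for
smoothing splines.  Measurement noise is treated as Gaussian.  Each variable
in each experiment gets its own fit (multiple shooting); repeated values at
a time point (different cells) enter as individual residual terms rather
than being pre-averaged.  The smoothing weight is either fixed or chosen by
generalized cross-validation (GCV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import TimeCourseDataset

__all__ = [
    "SmoothedTrajectory",
    "PenalizedSplineSmoother",
    "fit_collocation",
    "fit_experiment",
    "baseline_adjust",
    "trajectories_to_frame",
]

MAX_INTERIOR_KNOTS = 25  # knot cap: one knot per distinct sample time below this


@dataclass
class SmoothedTrajectory:
    """A fitted trajectory, evaluable anywhere on its domain.

    Attributes
    ----------
    spline : scipy.interpolate.BSpline
        The fitted curve.
    lam : float
        Smoothing weight actually used.
    rss : float
        Residual sum of squares at the sample points.
    n_samples : int
        Number of residual terms in the fit.
    """

    spline: BSpline
    lam: float
    rss: float
    n_samples: int

    @property
    def domain(self) -> tuple[float, float]:
        k = self.spline.k
        return (float(self.spline.t[k]), float(self.spline.t[-k - 1]))

    def __call__(self, t):
        return self.spline(np.asarray(t, dtype=float))

    def derivative(self, t):
        return self.spline.derivative()(np.asarray(t, dtype=float))

    def roughness(self, n_grid: int = 2048) -> float:
        """Integrated squared second derivative over the domain (dense grid)."""
        lo, hi = self.domain
        t = np.linspace(lo, hi, n_grid)
        d2 = self.spline.derivative(2)(t)
        return float(np.trapezoid(d2 ** 2, t))


def _basis_knots(times: np.ndarray, degree: int, n_interior: int | None,
                 domain: tuple[float, float]) -> np.ndarray:
    lo, hi = domain
    distinct = np.unique(times)
    if n_interior is None:
        interior = distinct[(distinct > lo) & (distinct < hi)]
        if interior.size > MAX_INTERIOR_KNOTS:
            qs = np.linspace(0, 1, MAX_INTERIOR_KNOTS + 2)[1:-1]
            interior = np.quantile(distinct, qs)
    else:
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def _design(knots: np.ndarray, degree: int, t: np.ndarray) -> np.ndarray:
    n_basis = len(knots) - degree - 1
    return BSpline.design_matrix(t, knots, degree, extrapolate=True).toarray()[:, :n_basis]


def _penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    """Gram matrix of basis second derivatives, exact per knot interval.

    Second derivatives are piecewise polynomials of degree d-2, so their
    pairwise products have degree 2(d-2); Gauss-Legendre with d-1 nodes per
    interval integrates them exactly (d >= 2).
    """
    n_basis = len(knots) - degree - 1
    if degree < 2:
        return np.zeros((n_basis, n_basis))
    eye = np.eye(n_basis)
    d2 = [BSpline(knots, eye[j], degree).derivative(2) for j in range(n_basis)]
    breaks = np.unique(knots)
    nodes, weights = np.polynomial.legendre.leggauss(max(degree - 1, 1))
    P = np.zeros((n_basis, n_basis))
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        t = mid + half * nodes
        vals = np.vstack([f(t) for f in d2])  # (n_basis, n_nodes)
        P += half * (vals * weights) @ vals.T
    return P


class PenalizedSplineSmoother(BaseEstimator, RegressorMixin):
    """Penalized B-spline regression of scattered (time, value) samples.

    Parameters
    ----------
    degree : int, default=3
        Spline degree (cubic by default).
    n_interior_knots : int or None, default=None
        Uniform interior knot count; ``None`` places a knot at every
        distinct sample time up to a cap of 25 (quantile-thinned beyond).
    lam : float or "gcv", default="gcv"
        Roughness weight; ``"gcv"`` minimizes generalized cross-validation
        over a log-spaced grid.
    domain : (float, float) or None, default=None
        Fit domain; defaults to the sample span.

    Attributes
    ----------
    spline_ : BSpline
        Fitted curve.
    lam_ : float
        Smoothing weight used.
    gcv_table_ : ndarray or None
        (lambda, GCV) rows when lam="gcv".
    """

    def __init__(self, degree: int = 3, n_interior_knots: int | None = None,
                 lam="gcv", domain=None):
        self.degree = degree
        self.n_interior_knots = n_interior_knots
        self.lam = lam
        self.domain = domain

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("t and y must have equal length")
        if np.unique(t).size < 2:
            raise ValueError("need samples at >= 2 distinct times")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite samples")
        domain = self.domain or (float(t.min()), float(t.max()))
        knots = _basis_knots(t, self.degree, self.n_interior_knots, domain)
        B = _design(knots, self.degree, t)
        P = _penalty(knots, self.degree)

        if self.lam == "gcv":
            grid = np.logspace(-8, 6, 29)
            scores = np.array([self._gcv(B, P, y, lam) for lam in grid])
            lam = float(grid[int(np.argmin(scores))])
            self.gcv_table_ = np.column_stack([grid, scores])
        else:
            lam = float(self.lam)
            if lam < 0:
                raise ValueError("smoothing weight must be >= 0")
            self.gcv_table_ = None

        coef = self._solve(B, P, y, lam)
        self.knots_ = knots
        self.coef_ = coef
        self.lam_ = lam
        self.spline_ = BSpline(knots, coef, self.degree, extrapolate=True)
        self.rss_ = float(np.sum((y - B @ coef) ** 2))
        self.n_samples_ = t.size
        return self

    @staticmethod
    def _solve(B, P, y, lam):
        if lam == 0:
            # minimum-norm least squares covers the rank-deficient
            # (saturated-basis) case
            return np.linalg.lstsq(B, y, rcond=None)[0]
        G = B.T @ B + lam * P
        if np.linalg.cond(G) < 1e8:
            try:
                return cho_solve(cho_factor(G), B.T @ y)
            except LinAlgError:
                pass
        # the normal equations lose precision once lam dominates; eliminate
        # the penalized directions in the eigenbasis of P (Schur complement
        # against its null space), which stays stable for any lam
        w, V = np.linalg.eigh(P)
        w = np.clip(w, 0, None)
        null = w <= 1e-12 * max(w.max(), 1.0)
        V0, Vp = V[:, null], V[:, ~null]
        M = V.T @ (B.T @ B) @ V
        b = V.T @ (B.T @ y)
        i0, ip = np.flatnonzero(null), np.flatnonzero(~null)
        Mpp = M[np.ix_(ip, ip)] + lam * np.diag(w[~null])
        sol_p = np.linalg.solve(Mpp, np.column_stack([b[ip], M[np.ix_(ip, i0)]]))
        S = M[np.ix_(i0, i0)] - M[np.ix_(i0, ip)] @ sol_p[:, 1:]
        rhs0 = b[i0] - M[np.ix_(i0, ip)] @ sol_p[:, 0]
        u0 = np.linalg.lstsq(S, rhs0, rcond=None)[0]
        up = sol_p[:, 0] - sol_p[:, 1:] @ u0
        return V0 @ u0 + Vp @ up

    @staticmethod
    def _gcv(B, P, y, lam):
        n = len(y)
        G = B.T @ B + lam * P
        try:
            sol = cho_solve(cho_factor(G), np.hstack([B.T @ y[:, None], B.T]))
        except LinAlgError:
            return np.inf
        coef, S = sol[:, 0], sol[:, 1:]
        rss = np.sum((y - B @ coef) ** 2)
        edf = float(np.einsum("ij,ji->", B, S))
        denom = n - edf
        if denom <= 1e-8:
            return np.inf
        return n * rss / denom ** 2

    def predict(self, t):
        check_is_fitted(self, "spline_")
        return self.spline_(np.asarray(t, dtype=float))

    def trajectory_(self) -> SmoothedTrajectory:
        check_is_fitted(self, "spline_")
        return SmoothedTrajectory(self.spline_, self.lam_, self.rss_, self.n_samples_)


def fit_collocation(times, values, degree: int = 3,
                    n_interior_knots: int | None = None, lam="gcv",
                    domain=None) -> SmoothedTrajectory:
    """Fit one variable's scattered samples; see :class:`PenalizedSplineSmoother`."""
    sm = PenalizedSplineSmoother(degree=degree, n_interior_knots=n_interior_knots,
                                 lam=lam, domain=domain)
    return sm.fit(times, values).trajectory_()


def fit_experiment(dataset: TimeCourseDataset, experiment, degree: int = 3,
                   n_interior_knots: int | None = None, lam="gcv",
                   domain=None) -> dict[str, SmoothedTrajectory]:
    """One independent trajectory per variable of one experiment.

    Variables with fewer than two distinct sample times are skipped with a
    warning and absent from the result.
    """
    out: dict[str, SmoothedTrajectory] = {}
    tab = dataset.experiment_table(experiment)
    if domain is None:
        domain = (float(tab["time"].min()), float(tab["time"].max()))
    for var in sorted(pd.unique(tab["variable"])):
        t, y = dataset.samples(experiment, var)
        if np.unique(t).size < 2:
            warnings.warn(
                f"variable {var!r} in experiment {experiment!r} has fewer than "
                "2 distinct time points; skipped", stacklevel=2)
            continue
        out[var] = fit_collocation(t, y, degree=degree,
                                   n_interior_knots=n_interior_knots,
                                   lam=lam, domain=domain)
    return out


def trajectories_to_frame(trajectories: dict[str, SmoothedTrajectory],
                          n_grid: int = 512) -> pd.DataFrame:
    """Evaluate fitted trajectories on a dense regular grid.

    Returns a wide table with a ``time`` column and one column per
    variable, suitable for CSV export or downstream plotting.
    """
    lo = min(tr.domain[0] for tr in trajectories.values())
    hi = max(tr.domain[1] for tr in trajectories.values())
    grid = np.linspace(lo, hi, n_grid)
    out = {"time": grid}
    for var in sorted(trajectories):
        out[var] = trajectories[var](grid)
    return pd.DataFrame(out)


def baseline_adjust(trajectory: SmoothedTrajectory,
                    n_grid: int = 2048) -> SmoothedTrajectory:
    """Subtract the trajectory minimum (the no-activity baseline).

    The minimum is located on a dense grid over the domain; because the
    clamped B-spline basis is a partition of unity, shifting every
    coefficient shifts the curve by the same constant.
    """
    lo, hi = trajectory.domain
    grid = np.linspace(lo, hi, n_grid)
    m = float(np.min(trajectory(grid)))
    shifted = BSpline(trajectory.spline.t, trajectory.spline.c - m,
                      trajectory.spline.k, extrapolate=True)
    return SmoothedTrajectory(shifted, trajectory.lam, trajectory.rss,
                              trajectory.n_samples)

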