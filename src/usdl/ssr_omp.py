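"""Sparse signal recovery by orthogonal matching pursuit (OMP).

Each variable's weak-form row ``z = Psi a + e`` is solved greedily: select
the (unit-normalized) column most correlated with the residual, refit all
active coefficients by least squares on the original columns — that refit
is OMP's orthogonalization — and repeat until the residual reaches an
estimate of the noise energy.  The noise energy is taken as ``(1 + alpha)``
times the l2 norm of the residual of the *complete* least-squares solution,
so larger ``alpha`` stops earlier and returns sparser supports.  A relative
criterion (stop when ``||r||^2 / ||z||^2 <= alpha``) is available as an
alternative; both are monotone in ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .weak_form import WeakSystem

__all__ = ["SparseSolution", "NoiseScaledOMP", "omp", "solve_system"]

_ZERO_RTOL = 1e-12  # residual below this times ||z|| counts as exactly solved


@dataclass
class SparseSolution:
    """Result of one sparse recovery: support, coefficients, residual trace."""

    support: list[int]
    coef: np.ndarray
    residual_norms: list[float]
    stopping_reason: str  # noise-floor | max-support | zero-residual
    alpha: float

    @property
    def size(self) -> int:
        return len(self.support)


class NoiseScaledOMP(BaseEstimator, RegressorMixin):
    """OMP with the noise-energy stopping rule.

    Parameters
    ----------
    alpha : float, default=0.1
        Stopping parameter (>= 0).  With ``criterion="noise-floor"`` the
        target residual is ``(1 + alpha) * ||z - Psi a_LS||_2`` where
        ``a_LS`` is the full least-squares solution; with
        ``criterion="relative"`` iteration stops once
        ``||r||^2 <= alpha * ||z||^2``.
    kmax : int or None, default=None
        Maximum support size; ``None`` means ``min(Q, 10)`` (sparsity
        prior).
    criterion : {"noise-floor", "relative"}

    Attributes
    ----------
    coef_ : (Q,) ndarray — zeros off the selected support.
    support_ : list of selected column indices, in selection order.
    residual_norms_ : residual l2 norm after each iteration (index 0 = ||z||).
    stopping_reason_ : {"noise-floor", "max-support", "zero-residual"}.
    """

    def __init__(self, alpha: float = 0.1, kmax: int | None = None,
                 criterion: str = "noise-floor"):
        self.alpha = alpha
        self.kmax = kmax
        self.criterion = criterion

    def fit(self, X, y):
        Psi = np.asarray(X, dtype=float)
        z = np.asarray(y, dtype=float).ravel()
        if Psi.ndim != 2 or Psi.shape[0] != z.size:
            raise ValueError(f"design shape {Psi.shape} incompatible with "
                             f"response length {z.size}")
        if not np.all(np.isfinite(Psi)) or not np.all(np.isfinite(z)):
            raise ValueError("non-finite entries in design or response")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.criterion not in ("noise-floor", "relative"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        Q = Psi.shape[1]
        kmax = min(Q, 10) if self.kmax is None else min(int(self.kmax), Q)

        norms = np.linalg.norm(Psi, axis=0)
        valid = norms > 0
        if not np.any(valid):
            raise ValueError("design matrix has no nonzero column")
        Psi_bar = np.where(valid, 1.0 / np.where(valid, norms, 1.0), 0.0) * Psi

        z_norm = np.linalg.norm(z)
        support: list[int] = []
        coef = np.zeros(Q)
        residual_norms = [float(z_norm)]
        if z_norm == 0.0:
            self._finish(support, coef, residual_norms, "zero-residual")
            return self

        if self.criterion == "noise-floor":
            a_ls = np.linalg.lstsq(Psi[:, valid], z, rcond=None)[0]
            eps = (1.0 + self.alpha) * np.linalg.norm(z - Psi[:, valid] @ a_ls)
        else:
            eps = np.sqrt(self.alpha) * z_norm
        floor = max(eps, _ZERO_RTOL * z_norm)

        r = z.copy()
        reason = "max-support"
        while True:
            r_norm = np.linalg.norm(r)
            if r_norm <= _ZERO_RTOL * z_norm:
                reason = "zero-residual"
                break
            if r_norm <= floor:
                reason = "noise-floor"
                break
            if len(support) >= kmax:
                reason = "max-support"
                break
            corr = np.abs(Psi_bar.T @ r)
            corr[~valid] = -np.inf
            corr[support] = -np.inf
            q = int(np.argmax(corr))  # ties break to the lowest index
            if not np.isfinite(corr[q]) or corr[q] <= 0:
                reason = "noise-floor"  # residual orthogonal to dictionary
                break
            support.append(q)
            sub = np.linalg.lstsq(Psi[:, support], z, rcond=None)[0]
            r = z - Psi[:, support] @ sub
            residual_norms.append(float(np.linalg.norm(r)))

        coef = np.zeros(Q)
        if support:
            coef[support] = np.linalg.lstsq(Psi[:, support], z, rcond=None)[0]
        self._finish(support, coef, residual_norms, reason)
        return self

    def _finish(self, support, coef, residual_norms, reason):
        self.support_ = support
        self.coef_ = coef
        self.residual_norms_ = residual_norms
        self.stopping_reason_ = reason
        self.n_iter_ = len(support)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_

    def solution_(self) -> SparseSolution:
        check_is_fitted(self, "coef_")
        return SparseSolution(list(self.support_), self.coef_.copy(),
                              list(self.residual_norms_),
                              self.stopping_reason_, float(self.alpha))


def omp(z: np.ndarray, Psi: np.ndarray, alpha: float = 0.1,
        kmax: int | None = None, criterion: str = "noise-floor") -> SparseSolution:
    """Solve ``z = Psi a + e`` sparsely; see :class:`NoiseScaledOMP`."""
    est = NoiseScaledOMP(alpha=alpha, kmax=kmax, criterion=criterion)
    return est.fit(Psi, z).solution_()


def solve_system(ws: WeakSystem, alpha: float = 0.1, kmax: int | None = None,
                 criterion: str = "noise-floor"
                 ) -> tuple[np.ndarray, dict[str, SparseSolution]]:
    """Per-variable OMP over a weak system: the estimated N x Q matrix A.

    Rows of variables with no usable experiment are left at zero with a
    warning; their solutions carry an empty support.
    """
    N, Q = len(ws.variables), len(ws.labels)
    A_hat = np.zeros((N, Q))
    solutions: dict[str, SparseSolution] = {}
    for i, var in enumerate(ws.variables):
        if var in ws.uninferable:
            warnings.warn(f"variable {var!r} has no usable experiments; "
                          "its equation is not inferable", stacklevel=2)
            solutions[var] = SparseSolution([], np.zeros(Q), [0.0],
                                            "noise-floor", float(alpha))
            continue
        sol = omp(ws.response_for(var), ws.design_for(var),
                  alpha=alpha, kmax=kmax, criterion=criterion)
        A_hat[i] = sol.coef
        solutions[var] = sol
    return A_hat, solutions
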