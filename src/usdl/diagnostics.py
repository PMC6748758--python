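"""Recoverability diagnostics: MIP, ERC, SNR, lambda_min, and the
noisy-recovery guarantee.

The mutual incoherence parameter (MIP) is the largest absolute cosine
similarity between distinct design columns: 0 for orthogonal designs, 1
when two columns are collinear.  It is an a priori indicator but can be
conservative — two collinear columns outside the solution do not actually
hurt recovery.  The exact recovery coefficient (ERC) of an index set S,

    ERC(S) = 1 - max_{q' not in S} || (Psibar_S^T Psibar_S)^-1
                                      Psibar_S^T psibar_q' ||_1

(over unit-normalized columns), measures only the collinearity of the
solution subspace with the remaining columns; ERC(true support) > 0 is
necessary for OMP (and convex relaxation) to recover the support exactly.
The true support being unknown in applications, ERC at the *estimated*
support serves as an a posteriori accuracy indicator.  Under noise,
recovery additionally requires every active coefficient to be large
enough relative to the noise; see :func:`guarantee_check`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError, eigh

__all__ = [
    "mip",
    "erc",
    "snr",
    "lambda_min",
    "guarantee_check",
    "GuaranteeReport",
    "RecoveryDiagnostics",
]

_RANK_RCOND = 1e-10


def _normalized_columns(Psi: np.ndarray, context: str) -> np.ndarray:
    Psi = np.asarray(Psi, dtype=float)
    if Psi.ndim != 2:
        raise ValueError(f"{context}: design must be a matrix")
    norms = np.linalg.norm(Psi, axis=0)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"{context}: column {int(zero[0])} is identically zero")
    return Psi / norms


def mip(Psi: np.ndarray) -> float:
    """Mutual incoherence: max absolute cosine between distinct columns."""
    Psi_bar = _normalized_columns(Psi, "mip")
    if Psi_bar.shape[1] < 2:
        raise ValueError("mip: need at least 2 columns")
    G = np.abs(Psi_bar.T @ Psi_bar)
    np.fill_diagonal(G, 0.0)
    m = float(min(G.max(), 1.0))
    # collinear columns are cosine 1 exactly; absorb float rounding
    return 1.0 if m > 1.0 - 1e-12 else m


def _gram_solve(Psi_bar_S: np.ndarray, rhs: np.ndarray, context: str) -> np.ndarray:
    G = Psi_bar_S.T @ Psi_bar_S
    try:
        c = cho_factor(G)
    except LinAlgError:
        raise ValueError(f"{context}: support columns are rank deficient") from None
    # a Cholesky that succeeds can still hide near-singularity
    if np.linalg.cond(G) > 1.0 / _RANK_RCOND:
        raise ValueError(f"{context}: support columns are rank deficient")
    return cho_solve(c, rhs)


def erc(Psi: np.ndarray, S) -> float:
    """Exact recovery coefficient of index set S (1 if S is all columns)."""
    S = sorted(set(int(q) for q in S))
    Psi_bar = _normalized_columns(Psi, "erc")
    Q = Psi_bar.shape[1]
    if not S:
        raise ValueError("erc: index set must be nonempty")
    if S[0] < 0 or S[-1] >= Q:
        raise ValueError(f"erc: index set out of range for {Q} columns")
    off = [q for q in range(Q) if q not in S]
    if not off:
        return 1.0
    sol = _gram_solve(Psi_bar[:, S], Psi_bar[:, S].T @ Psi_bar[:, off], "erc")
    return float(1.0 - np.abs(sol).sum(axis=0).max())


def snr(Psi: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Per-column signal-to-noise ratios ||psi_q||_2 / ||e||_2.

    A zero noise vector yields an infinite-SNR sentinel for every column.
    """
    Psi = np.asarray(Psi, dtype=float)
    e_norm = np.linalg.norm(np.asarray(e, dtype=float))
    norms = np.linalg.norm(Psi, axis=0)
    if e_norm == 0:
        return np.full(norms.shape, np.inf)
    return norms / e_norm


def lambda_min(Psi: np.ndarray, S) -> float:
    """Smallest eigenvalue of the normalized support columns' Gram matrix.

    In (0, 1] for full-rank normalized atoms; 0 (with a warning-free
    clamp) under rank deficiency.
    """
    S = sorted(set(int(q) for q in S))
    if not S:
        raise ValueError("lambda_min: index set must be nonempty")
    Psi_bar = _normalized_columns(Psi, "lambda_min")
    G = Psi_bar[:, S].T @ Psi_bar[:, S]
    w = eigh(G, eigvals_only=True)
    return float(max(w[0], 0.0))


@dataclass
class GuaranteeReport:
    """Per-coefficient audit of the noisy-recovery coefficient condition."""

    available: bool
    erc: float
    lam_min: float
    indices: list[int]
    values: np.ndarray      # |a_q| on the support
    thresholds: np.ndarray  # 2 / (SNR(q) * ERC * lambda_min)
    passed: np.ndarray      # elementwise booleans

    @property
    def all_passed(self) -> bool:
        return self.available and bool(np.all(self.passed))


def guarantee_check(a: np.ndarray, Psi: np.ndarray, S, e: np.ndarray) -> GuaranteeReport:
    """Check the coefficient-magnitude condition for exact recovery under noise.

    For every support index q the condition
    ``|a_q| >= 2 / (SNR(q) * ERC(S) * lambda_min(S))`` is evaluated; with
    vanishing noise the thresholds tend to zero and the check is vacuously
    satisfied.  If ``ERC(S) <= 0`` the necessary condition for recovery
    already fails and the guarantee is reported unavailable.
    """
    a = np.asarray(a, dtype=float).ravel()
    S = sorted(set(int(q) for q in S))
    e_val = erc(Psi, S)
    lam = lambda_min(Psi, S)
    if e_val <= 0 or lam <= 0:
        k = len(S)
        return GuaranteeReport(False, e_val, lam, S, np.abs(a[S]),
                               np.full(k, np.inf), np.zeros(k, dtype=bool))
    s = snr(Psi, e)[S]
    with np.errstate(divide="ignore"):
        thresholds = 2.0 / (s * e_val * lam)  # zero when SNR is infinite
    values = np.abs(a[S])
    return GuaranteeReport(True, e_val, lam, S, values, thresholds,
                           values >= thresholds)


@dataclass
class RecoveryDiagnostics:
    """Bundle of recoverability metrics for one assembled system."""

    mip: float
    erc_per_variable: dict[str, float | None]
    supports: dict[str, list[int]]
    lambda_min_per_variable: dict[str, float | None]
    residual_norm_per_variable: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "mip": self.mip,
            "erc": self.erc_per_variable,
            "supports": self.supports,
            "lambda_min": self.lambda_min_per_variable,
            "residual_norm": self.residual_norm_per_variable,
        }
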