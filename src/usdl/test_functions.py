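"""Families of smooth test functions for the weak-formulation inner products.

The weak formulation projects a differential equation onto a finite set of
smooth test functions ``phi_m`` on a time interval ``[0, T]``.  Because the
test functions are known analytically, their derivatives are exact — this is
what lets the method avoid differentiating noisy data.  Every family here
therefore exposes both ``values`` and ``derivatives`` with closed-form
implementations (B-splines differentiate their piecewise polynomials
exactly; nothing uses finite differences).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "TestFunctionFamily",
    "FourierFamily",
    "PeakyFourierFamily",
    "BSplineFamily",
    "CustomFamily",
    "make_fourier_family",
    "make_peaky_fourier_family",
    "make_bspline_family",
    "family_from_spec",
]


class TestFunctionFamily:
    """Abstract family of M smooth test functions on [0, T].

    Subclasses implement :meth:`values` and :meth:`derivatives`, each
    returning an ``(M, len(t))`` array for a time grid ``t``.
    """

    kind: str = "custom"

    def __init__(self, T: float, size: int):
        if not np.isfinite(T) or T <= 0:
            raise ValueError(f"final time T must be positive, got {T}")
        if size < 1:
            raise ValueError(f"family size must be >= 1, got {size}")
        self.T = float(T)
        self.size = int(size)

    @property
    def domain(self) -> tuple[float, float]:
        return (0.0, self.T)

    def values(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def derivatives(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _check_t(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if t.ndim != 1:
            raise ValueError("time grid must be one-dimensional")
        return t

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(T={self.T}, size={self.size})"


class FourierFamily(TestFunctionFamily):
    """Constant plus sine/cosine harmonics of the record length T.

    Member order is fixed: ``1, sin(2*pi*t/T), cos(2*pi*t/T),
    sin(4*pi*t/T), cos(4*pi*t/T), ...`` so that design-matrix rows are
    reproducible across runs.  The fundamental period is the full record
    length; the data are not assumed periodic.
    """

    kind = "fourier"

    def __init__(self, T: float, K: int):
        if int(K) != K or K < 0:
            raise ValueError(f"harmonic order K must be a non-negative integer, got {K}")
        self.K = int(K)
        super().__init__(T, 2 * self.K + 1)

    def _angular(self) -> np.ndarray:
        # angular frequency per harmonic k = 1..K
        return 2.0 * np.pi * np.arange(1, self.K + 1) / self.T

    def values(self, t) -> np.ndarray:
        t = self._check_t(t)
        out = np.empty((self.size, t.size))
        out[0] = 1.0
        if self.K:
            wt = np.outer(self._angular(), t)
            out[1::2] = np.sin(wt)
            out[2::2] = np.cos(wt)
        return out

    def derivatives(self, t) -> np.ndarray:
        t = self._check_t(t)
        out = np.zeros((self.size, t.size))
        if self.K:
            w = self._angular()
            wt = np.outer(w, t)
            out[1::2] = w[:, None] * np.cos(wt)
            out[2::2] = -w[:, None] * np.sin(wt)
        return out


class PeakyFourierFamily(TestFunctionFamily):
    """Periodic, sharply localized bumps ("peaky" Fourier modes).

    Members are von-Mises-style bumps ``exp(kappa*(cos(2*pi*k*(t-c)/T) - 1))``
    for harmonics ``k = 1..K`` at two phase offsets per harmonic
    (``c = T/(4k)`` and ``c = 3T/(4k)``, half a period apart), preceded by
    the constant function.  They are smooth and periodic like Fourier modes
    but concentrate mass near their centers, which sharpens the separation
    of trajectories whose correlations differ only over short time lags.
    The quarter-period offsets keep every peak a quarter period away from
    the record boundaries, so for moderately sharp ``kappa`` the non-constant
    members effectively vanish at 0 and T and contribute no boundary term.
    As ``kappa -> 0`` every bump flattens to the constant 1.
    """

    kind = "peaky_fourier"

    def __init__(self, T: float, K: int, kappa: float):
        if int(K) != K or K < 1:
            raise ValueError(f"order K must be a positive integer, got {K}")
        if not np.isfinite(kappa) or kappa <= 0:
            raise ValueError(f"sharpness kappa must be positive, got {kappa}")
        self.K = int(K)
        self.kappa = float(kappa)
        super().__init__(T, 2 * self.K + 1)
        # (harmonic k, center c) per non-constant member, constant excluded
        self._k = np.repeat(np.arange(1, self.K + 1), 2)
        self._c = np.empty(2 * self.K)
        self._c[0::2] = self.T / (4.0 * np.arange(1, self.K + 1))
        self._c[1::2] = 3.0 * self.T / (4.0 * np.arange(1, self.K + 1))

    def centers(self) -> np.ndarray:
        """Peak centers of the non-constant members, in member order."""
        return self._c.copy()

    def _phase(self, t: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * self._k / self.T
        return w[:, None] * (t[None, :] - self._c[:, None]), w

    def values(self, t) -> np.ndarray:
        t = self._check_t(t)
        out = np.empty((self.size, t.size))
        out[0] = 1.0
        theta, _ = self._phase(t)
        out[1:] = np.exp(self.kappa * (np.cos(theta) - 1.0))
        return out

    def derivatives(self, t) -> np.ndarray:
        t = self._check_t(t)
        out = np.zeros((self.size, t.size))
        theta, w = self._phase(t)
        bump = np.exp(self.kappa * (np.cos(theta) - 1.0))
        out[1:] = -self.kappa * w[:, None] * np.sin(theta) * bump
        return out


class BSplineFamily(TestFunctionFamily):
    """B-spline basis on a uniform knot grid over [0, T].

    ``K`` interior knots, polynomial degree >= 1 (degree 0 would have a
    distributional derivative, violating the exact-derivative contract).
    Derivatives are the exact piecewise-polynomial derivatives.
    """

    kind = "bspline"

    def __init__(self, T: float, K: int, degree: int):
        if int(degree) != degree or degree < 1:
            raise ValueError(f"spline degree must be an integer >= 1, got {degree}")
        if int(K) != K or K < 0:
            raise ValueError(f"interior knot count must be >= 0, got {K}")
        self.degree = int(degree)
        self.K = int(K)
        interior = np.linspace(0.0, T, self.K + 2)[1:-1]
        self._knots = np.concatenate(
            [np.zeros(self.degree + 1), interior, np.full(self.degree + 1, T)]
        )
        size = len(self._knots) - self.degree - 1
        super().__init__(T, size)
        eye = np.eye(size)
        self._splines = [BSpline(self._knots, eye[m], self.degree) for m in range(size)]
        self._dsplines = [s.derivative() for s in self._splines]

    @property
    def knots(self) -> np.ndarray:
        return self._knots.copy()

    def values(self, t) -> np.ndarray:
        t = self._check_t(t)
        return np.vstack([s(t) for s in self._splines])

    def derivatives(self, t) -> np.ndarray:
        t = self._check_t(t)
        return np.vstack([s(t) for s in self._dsplines])


class CustomFamily(TestFunctionFamily):
    """User-supplied test functions with user-supplied exact derivatives."""

    def __init__(self, T: float, funcs: Sequence, dfuncs: Sequence):
        if len(funcs) != len(dfuncs):
            raise ValueError("need one derivative per member")
        if not funcs:
            raise ValueError("at least one member required")
        self._funcs = list(funcs)
        self._dfuncs = list(dfuncs)
        super().__init__(T, len(funcs))

    def values(self, t) -> np.ndarray:
        t = self._check_t(t)
        return np.vstack([np.broadcast_to(f(t), t.shape) for f in self._funcs])

    def derivatives(self, t) -> np.ndarray:
        t = self._check_t(t)
        return np.vstack([np.broadcast_to(f(t), t.shape) for f in self._dfuncs])


def make_fourier_family(T: float, K: int) -> FourierFamily:
    """Fourier test functions: the constant plus K sine/cosine pairs (M = 2K+1)."""
    return FourierFamily(T, K)


def make_peaky_fourier_family(T: float, K: int, kappa: float) -> PeakyFourierFamily:
    """Localized periodic bumps: constant plus 2K peaks of sharpness kappa."""
    return PeakyFourierFamily(T, K, kappa)


def make_bspline_family(T: float, K: int, degree: int = 3) -> BSplineFamily:
    """B-spline basis with K uniform interior knots and the given degree."""
    return BSplineFamily(T, K, degree)


def family_from_spec(spec: str, T: float) -> TestFunctionFamily:
    """Build a family from a CLI/config string.

    Formats: ``"fourier:K"``, ``"peaky:K,kappa"``, ``"bspline:K,degree"``.
    """
    try:
        kind, _, args = spec.partition(":")
        kind = kind.strip().lower()
        if kind == "fourier":
            return FourierFamily(T, int(args))
        if kind == "peaky":
            k, kappa = args.split(",")
            return PeakyFourierFamily(T, int(k), float(kappa))
        if kind == "bspline":
            k, degree = args.split(",")
            return BSplineFamily(T, int(k), int(degree))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"cannot parse test-function spec {spec!r}: {exc}") from None
    raise ValueError(f"unknown test-function kind {kind!r}")
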