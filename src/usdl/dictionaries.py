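"""Candidate-function dictionaries spanning the hypothesized dynamics.

The dynamics are assumed linear in their parameters: ``dx_n/dt`` is a sparse
linear combination of dictionary atoms ``psi_q(x)``.  Under mass-action
kinetics a single-reactant assumption gives the linear dictionary
(``psi(x) = x``, Q = N) and a two-reactant assumption appends all quadratic
monomials, giving Q = (N+3)N/2.  Atom order is fixed (linear terms, then
upper-triangular products row by row) so coefficient indices are portable.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Dictionary",
    "make_linear_dictionary",
    "make_quadratic_dictionary",
    "make_custom_dictionary",
    "evaluate_dictionary",
    "dictionary_from_spec",
]


class Dictionary:
    """Ordered, labeled collection of scalar functions of the state.

    Parameters
    ----------
    arity : int
        State dimension N the atoms accept.
    labels : sequence of str
        Unique human-readable atom labels, e.g. ``"x3"`` or ``"x1*x2"``.
    funcs : sequence of callables
        Each maps an ``(n_times, N)`` state array to ``(n_times,)`` values.
    kind : str
        Informational tag ("linear", "quadratic", "custom").
    """

    def __init__(self, arity: int, labels: Sequence[str],
                 funcs: Sequence[Callable[[np.ndarray], np.ndarray]],
                 kind: str = "custom"):
        if arity < 1:
            raise ValueError(f"state dimension must be >= 1, got {arity}")
        labels = list(labels)
        if not labels:
            raise ValueError("dictionary needs at least one member")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate dictionary labels: {dupes}")
        if len(labels) != len(funcs):
            raise ValueError("one label per member required")
        self.arity = int(arity)
        self.labels = labels
        self.funcs = list(funcs)
        self.kind = kind

    @property
    def size(self) -> int:
        return len(self.labels)

    def evaluate(self, states: np.ndarray) -> np.ndarray:
        """Evaluate all atoms on time-indexed states.

        ``states`` is ``(n_times, N)`` (a single N-vector is promoted to one
        row); returns ``(n_times, Q)`` with columns in member order.
        """
        states = np.asarray(states, dtype=float)
        if states.ndim == 1:
            states = states[None, :]
        if states.ndim != 2 or states.shape[1] != self.arity:
            raise ValueError(
                f"states must be (n_times, {self.arity}), got {states.shape}")
        if not np.all(np.isfinite(states)):
            bad = np.argwhere(~np.isfinite(states))[0]
            raise ValueError(
                f"non-finite state value at time index {bad[0]}, variable {bad[1]}")
        out = np.column_stack([np.broadcast_to(f(states), (states.shape[0],))
                               for f in self.funcs])
        return out

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dictionary(kind={self.kind!r}, N={self.arity}, Q={self.size})"


def _default_names(N: int, names: Sequence[str] | None) -> list[str]:
    if names is None:
        return [f"x{i + 1}" for i in range(N)]
    names = list(names)
    if len(names) != N:
        raise ValueError(f"expected {N} variable names, got {len(names)}")
    return names


def make_linear_dictionary(N: int, names: Sequence[str] | None = None) -> Dictionary:
    """Identity dictionary psi(x) = x (single-reactant mass action): Q = N."""
    names = _default_names(N, names)
    funcs = [(lambda q: (lambda s: s[:, q]))(q) for q in range(N)]
    return Dictionary(N, names, funcs, kind="linear")


def make_quadratic_dictionary(N: int, names: Sequence[str] | None = None) -> Dictionary:
    """Linear plus all quadratic monomials x_i*x_j (i <= j): Q = (N+3)N/2.

    Order: x_1..x_N, then x_1*x_1..x_1*x_N, x_2*x_2..x_2*x_N, ..., x_N*x_N.
    """
    names = _default_names(N, names)
    labels = list(names)
    funcs = [(lambda q: (lambda s: s[:, q]))(q) for q in range(N)]
    for i in range(N):
        for j in range(i, N):
            labels.append(f"{names[i]}*{names[j]}")
            funcs.append((lambda a, b: (lambda s: s[:, a] * s[:, b]))(i, j))
    return Dictionary(N, labels, funcs, kind="quadratic")


def make_custom_dictionary(members: Sequence[tuple[str, Callable]], N: int) -> Dictionary:
    """Dictionary from (label, function) pairs; functions act on (n_times, N)."""
    if not members:
        raise ValueError("custom dictionary needs at least one member")
    labels = [m[0] for m in members]
    funcs = [m[1] for m in members]
    return Dictionary(N, labels, funcs, kind="custom")


def evaluate_dictionary(dictionary: Dictionary, states: np.ndarray) -> np.ndarray:
    """Matrix of psi_q(x(t_i)) values, columns in member order."""
    return dictionary.evaluate(states)


def drop_near_constant_columns(dictionary: Dictionary, states: np.ndarray,
                               tol: float = 1e-12) -> Dictionary:
    """Return a dictionary without atoms that are near-constant on the data.

    Constant-over-time atoms add collinearity with the constant direction
    (especially with quadratic terms) and can imperil recovery accuracy, so
    callers may opt to prune them; pruning is never automatic.
    """
    vals = dictionary.evaluate(states)
    keep = np.var(vals, axis=0) > tol
    if not np.any(keep):
        raise ValueError("all dictionary atoms are near-constant on these data")
    return Dictionary(
        dictionary.arity,
        [l for l, k in zip(dictionary.labels, keep) if k],
        [f for f, k in zip(dictionary.funcs, keep) if k],
        kind=dictionary.kind,
    )


def dictionary_from_spec(spec: str, N: int,
                         names: Sequence[str] | None = None) -> Dictionary:
    """Build a dictionary from a CLI/config string: "linear" or "quadratic"."""
    kind = spec.strip().lower()
    if kind == "linear":
        return make_linear_dictionary(N, names)
    if kind == "quadratic":
        return make_quadratic_dictionary(N, names)
    raise ValueError(f"unknown dictionary spec {spec!r}")
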