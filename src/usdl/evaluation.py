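"""Edge sets derived from coefficient matrices, and network scoring.

The nonzero pattern of the estimated coefficient matrix defines the
inferred network: a positive coefficient of atom ``q`` in variable ``n``'s
equation means the atom up-regulates ``n`` (drawn as an arrow), a negative
one means down-regulation (drawn as a bar).  For a linear dictionary the
atoms are the variables themselves and the edges are ordinary directed
variable-to-variable edges; for richer dictionaries an edge is labeled by
its atom (a hyper-edge such as ``x1*x2 -> x3``).

Scoring compares directed supports.  By default the sign is ignored
(support recovery) and self-loops (diagonal entries, which model
degradation) are excluded; both choices can be flipped.  An empty
prediction scores precision 1 and recall 0, so over-sparse solutions are
penalized through recall only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["EdgeSet", "edges_from_matrix", "precision_recall", "rmse"]


@dataclass
class EdgeSet:
    """Directed signed edges keyed by (source label, target variable)."""

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    includes_diagonal: bool = False

    def add(self, source: str, target: str, coefficient: float) -> None:
        key = (source, target)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key}")
        self.edges[key] = float(coefficient)

    def support(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def signed_support(self) -> set[tuple[str, str, int]]:
        return {(s, t, int(np.sign(c))) for (s, t), c in self.edges.items()}

    def items(self) -> Iterator:
        return iter(sorted(self.edges.items()))

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, key) -> bool:
        return tuple(key) in self.edges

    def to_frame(self) -> pd.DataFrame:
        rows = [{"source": s, "target": t, "coefficient": c,
                 "sign": int(np.sign(c))} for (s, t), c in self.items()]
        return pd.DataFrame(rows, columns=["source", "target", "coefficient",
                                           "sign"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   includes_diagonal: bool = False) -> "EdgeSet":
        es = cls(includes_diagonal=includes_diagonal)
        for _, row in frame.iterrows():
            es.add(str(row["source"]), str(row["target"]),
                   float(row["coefficient"]))
        return es

    @classmethod
    def from_tsv(cls, path) -> "EdgeSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def edges_from_matrix(A_hat: np.ndarray, labels, variables,
                      include_diagonal: bool = False,
                      tol: float = 0.0) -> EdgeSet:
    """One edge per nonzero coefficient, atom label -> target variable.

    Diagonal means an atom whose label equals the target variable (a
    self-loop, e.g. first-order degradation); excluded unless requested.
    """
    A_hat = np.asarray(A_hat, dtype=float)
    labels, variables = list(labels), list(variables)
    if A_hat.shape != (len(variables), len(labels)):
        raise ValueError(f"matrix shape {A_hat.shape} does not match "
                         f"{len(variables)} variables x {len(labels)} labels")
    es = EdgeSet(includes_diagonal=include_diagonal)
    for i, var in enumerate(variables):
        for q, lab in enumerate(labels):
            if abs(A_hat[i, q]) <= tol:
                continue
            if not include_diagonal and lab == var:
                continue
            es.add(lab, var, A_hat[i, q])
    return es


def precision_recall(predicted: EdgeSet, truth: EdgeSet,
                     signed: bool = False) -> tuple[float, float, float]:
    """(precision, recall, F1) over directed support.

    ``signed=True`` additionally requires the coefficient sign to match.
    Conventions: empty prediction -> precision 1; empty truth -> recall 1;
    F1 is 0 whenever precision + recall is 0.
    """
    pred = predicted.signed_support() if signed else predicted.support()
    true = truth.signed_support() if signed else truth.support()
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(true) if true else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def rmse(A_hat: np.ndarray, A_true: np.ndarray) -> float:
    """Root mean squared error over all coefficient-matrix entries."""
    A_hat = np.asarray(A_hat, dtype=float)
    A_true = np.asarray(A_true, dtype=float)
    if A_hat.shape != A_true.shape:
        raise ValueError(f"shape mismatch: {A_hat.shape} vs {A_true.shape}")
    return float(np.sqrt(np.mean((A_hat - A_true) ** 2)))
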