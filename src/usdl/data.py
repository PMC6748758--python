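"""Long-format temporal measurement tables and intervention annotations.

Two measurement regimes are supported by the same container:

* repeated measurements (time-series): the same object is measured at every
  sampling point, so each (experiment, variable) pair traces a trajectory;
* non-repeated measurements (time-course): every sample destroys the
  measured object (e.g. a cell in mass cytometry), so values at different
  times come from different objects drawn from a common distribution and a
  trajectory must first be reconstructed by collocation.

The on-disk format is a delimited long table with columns
``experiment, time, variable, value`` plus an optional interventions table
``experiment, variable, type`` with type in {inhibition, activation, none}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeCourseDataset", "TimeSeriesCollection", "INTERVENTION_TYPES"]

INTERVENTION_TYPES = ("inhibition", "activation", "none")

_COLUMNS = ["experiment", "time", "variable", "value"]


@dataclass
class TimeCourseDataset:
    """Measurements in long format with per-experiment interventions.

    Parameters
    ----------
    data : DataFrame
        Columns ``experiment, time, variable, value``.
    interventions : DataFrame, optional
        Columns ``experiment, variable, type``; rows with type ``none``
        are ignored.
    """

    data: pd.DataFrame
    interventions: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"data table missing columns: {missing}")
        self.data = self.data[_COLUMNS].copy()
        self.data["time"] = self.data["time"].astype(float)
        self.data["value"] = self.data["value"].astype(float)
        times = self.data["time"].to_numpy()
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("times must be finite and nonnegative")
        if self.interventions is not None:
            need = ["experiment", "variable", "type"]
            missing = [c for c in need if c not in self.interventions.columns]
            if missing:
                raise ValueError(f"interventions table missing columns: {missing}")
            bad = set(self.interventions["type"]) - set(INTERVENTION_TYPES)
            if bad:
                raise ValueError(f"unknown intervention types: {sorted(bad)}")

    @property
    def experiments(self) -> list:
        return list(pd.unique(self.data["experiment"]))

    @property
    def variables(self) -> list[str]:
        return sorted(pd.unique(self.data["variable"]))

    def experiment_table(self, experiment) -> pd.DataFrame:
        tab = self.data[self.data["experiment"] == experiment]
        if tab.empty:
            raise KeyError(f"no such experiment: {experiment!r}")
        return tab

    def samples(self, experiment, variable) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for one variable in one experiment, time-sorted."""
        tab = self.experiment_table(experiment)
        tab = tab[tab["variable"] == variable].sort_values("time")
        return tab["time"].to_numpy(), tab["value"].to_numpy()

    def intervened(self, experiment, kind: str | None = None) -> set[str]:
        """Variables intervened on in an experiment (optionally by type)."""
        if self.interventions is None:
            return set()
        tab = self.interventions
        tab = tab[(tab["experiment"] == experiment) & (tab["type"] != "none")]
        if kind is not None:
            tab = tab[tab["type"] == kind]
        return set(tab["variable"])

    def subset_experiments(self, experiments) -> "TimeCourseDataset":
        keep = self.data["experiment"].isin(list(experiments))
        iv = None
        if self.interventions is not None:
            iv = self.interventions[
                self.interventions["experiment"].isin(list(experiments))
            ].reset_index(drop=True)
        return TimeCourseDataset(self.data[keep].reset_index(drop=True), iv)

    def subset_times(self, experiment_times: dict) -> "TimeCourseDataset":
        """Keep only listed times per experiment (stability subsampling)."""
        masks = []
        for exp, times in experiment_times.items():
            m = (self.data["experiment"] == exp) & self.data["time"].isin(times)
            masks.append(m)
        keep = np.logical_or.reduce(masks) if masks else np.zeros(len(self.data), bool)
        return TimeCourseDataset(self.data[keep].reset_index(drop=True),
                                 self.interventions)

    # ---- I/O -----------------------------------------------------------
    def to_csv(self, data_path, interventions_path=None) -> None:
        self.data.to_csv(data_path, index=False)
        if interventions_path is not None and self.interventions is not None:
            self.interventions.to_csv(interventions_path, index=False)

    @classmethod
    def read_csv(cls, data_path, interventions_path=None, sep=",") -> "TimeCourseDataset":
        data = pd.read_csv(data_path, sep=sep)
        iv = pd.read_csv(interventions_path, sep=sep) if interventions_path else None
        return cls(data, iv)

    @classmethod
    def from_collection(cls, coll: "TimeSeriesCollection") -> "TimeCourseDataset":
        return cls.from_arrays(coll.times, coll.paths, coll.variables)

    @classmethod
    def from_arrays(cls, times: np.ndarray, paths: np.ndarray,
                    variables=None, experiments=None) -> "TimeCourseDataset":
        """Build a repeated-measurement dataset from a (P, n_times, N) array."""
        paths = np.asarray(paths, dtype=float)
        if paths.ndim == 2:
            paths = paths[None]
        P, n_times, N = paths.shape
        if variables is None:
            variables = [f"x{i + 1}" for i in range(N)]
        if experiments is None:
            experiments = [f"path{p + 1}" for p in range(P)]
        frames = []
        for p, exp in enumerate(experiments):
            frames.append(pd.DataFrame({
                "experiment": exp,
                "time": np.repeat(times, N),
                "variable": np.tile(variables, n_times),
                "value": paths[p].ravel(),
            }))
        return cls(pd.concat(frames, ignore_index=True))

@dataclass
class TimeSeriesCollection:
    """Repeated-measurement paths on a shared time grid.

    A lightweight array container for simulator output and large
    time-series datasets: ``paths`` has shape (P, n_times, N) with one
    experiment (path) per leading index.  Converts losslessly to the long
    format when table semantics are needed.
    """

    times: np.ndarray
    paths: np.ndarray
    variables: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.paths = np.asarray(self.paths, dtype=float)
        if self.paths.ndim == 2:
            self.paths = self.paths[None]
        P, n_times, N = self.paths.shape
        if self.times.shape != (n_times,):
            raise ValueError("times length must match paths' second axis")
        if not self.variables:
            self.variables = [f"x{i + 1}" for i in range(N)]
        if len(self.variables) != N:
            raise ValueError("one variable name per state dimension required")

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    def subset_paths(self, indices) -> "TimeSeriesCollection":
        return TimeSeriesCollection(self.times, self.paths[list(indices)],
                                    list(self.variables))

    def to_dataset(self) -> TimeCourseDataset:
        return TimeCourseDataset.from_arrays(self.times, self.paths,
                                             self.variables)
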