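"""Fluorescence observable, scale factor and weighted residual objective.

The live-imaging observable is nuclear fluorescence, taken to report the sum
of free nuclear dl and nuclear dl/Cact complex (both carry the fluorophore):
``Y_hk = U_nuc + W_nuc`` sampled at data nucleus ``h`` and time ``k``.  The
simulation is compared to the data ``X_hk +- dX_hk`` after a single global
scale factor ``S = <XY> / <Y^2>`` (the ordinary-least-squares minimizer of
``sum (X - S Y)^2`` over all grid cells), and the goodness of fit is the
uncertainty-weighted residual sum of squares
``rss = sum_hk ((X_hk - S Y_hk) / dX_hk)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Trajectory

__all__ = [
    "SpatioTemporalDataset",
    "ObjectiveValue",
    "fluorescence_signal",
    "scale_factor",
    "weighted_rss",
    "evaluate_objective",
]

DATASET_COLUMNS = ("time_min", "cycle", "nucleus_index", "dv_position", "X", "dX")


@dataclass
class SpatioTemporalDataset:
    """Nuclear-fluorescence observations on a (nucleus, time) grid.

    Rows index nuclei at NC14 resolution (``dv_positions``), columns index
    interphase time points in minutes with a per-time nuclear-cycle
    annotation.  ``dX`` holds strictly positive measurement uncertainties.
    """

    X: np.ndarray
    dX: np.ndarray
    dv_positions: np.ndarray
    times: np.ndarray
    cycles: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.dX = np.asarray(self.dX, dtype=float)
        self.dv_positions = np.asarray(self.dv_positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.cycles = np.asarray(self.cycles, dtype=int)
        nh, nk = self.X.shape
        if self.dX.shape != (nh, nk):
            raise ValueError("X and dX shapes disagree")
        if len(self.dv_positions) != nh or len(self.times) != nk:
            raise ValueError("grid axes do not match X")
        if len(self.cycles) != nk:
            raise ValueError("cycle annotation must match times")
        if not np.all(self.dX > 0):
            raise ValueError("dX must be strictly positive")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_nuclei(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        nh, nk = self.X.shape
        h, k = np.meshgrid(np.arange(nh), np.arange(nk), indexing="ij")
        return pd.DataFrame(
            {
                "time_min": self.times[k.ravel()],
                "cycle": self.cycles[k.ravel()],
                "nucleus_index": h.ravel(),
                "dv_position": self.dv_positions[h.ravel()],
                "X": self.X.ravel(),
                "dX": self.dX.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpatioTemporalDataset":
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset is missing columns {sorted(missing)}")
        times = np.sort(df["time_min"].unique())
        nuclei = np.sort(df["nucleus_index"].unique())
        nh, nk = len(nuclei), len(times)
        if len(df) != nh * nk:
            raise ValueError("dataset grid is incomplete")
        piv = df.pivot(index="nucleus_index", columns="time_min")
        cyc = df.groupby("time_min")["cycle"].first().loc[times].to_numpy()
        pos = df.groupby("nucleus_index")["dv_position"].first().loc[nuclei].to_numpy()
        return cls(
            X=piv["X"].to_numpy(),
            dX=piv["dX"].to_numpy(),
            dv_positions=pos,
            times=times,
            cycles=cyc,
        )

    @classmethod
    def from_csv(cls, path) -> "SpatioTemporalDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ObjectiveValue:
    """Scale factor and weighted residual sum for one parameter set."""

    S: float
    rss: float


def fluorescence_signal(
    traj: Trajectory, dataset: SpatioTemporalDataset, observable: str = "total"
) -> np.ndarray:
    """Simulated fluorescence ``Y_hk`` on the dataset grid.

    ``observable="total"`` is the standard ``U_nuc + W_nuc`` read-out;
    ``"free"`` restricts to free nuclear dl, the natural choice when the
    classic variant (no nuclear complex) is fit.  Data nuclei are mapped to
    their containing simulated compartment at each cycle, so early coarse
    cycles are compared at NC14 grid resolution.
    """
    return traj.nuclear_signal_on_grid(
        dataset.dv_positions, dataset.times, component=observable
    )


def scale_factor(X: np.ndarray, Y: np.ndarray) -> float:
    """OLS estimate ``S = <XY> / <Y^2>`` of the fluorescence scale."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    denom = np.mean(Y**2)
    if denom == 0:
        raise ValueError("Y is identically zero; scale factor undefined")
    return float(np.mean(X * Y) / denom)


def weighted_rss(X: np.ndarray, dX: np.ndarray, Y: np.ndarray, S: float) -> float:
    """Uncertainty-weighted residual sum ``sum ((X - S*Y)/dX)^2``."""
    X, dX, Y = (np.asarray(a, dtype=float) for a in (X, dX, Y))
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y)) and np.isfinite(S)):
        raise ValueError("non-finite inputs to weighted_rss")
    r = (X - S * Y) / dX
    return float(np.sum(r * r))


def evaluate_objective(
    traj: Trajectory, dataset: SpatioTemporalDataset, observable: str = "total"
) -> ObjectiveValue:
    """Scale-then-score a trajectory against a dataset."""
    Y = fluorescence_signal(traj, dataset, observable=observable)
    S = scale_factor(dataset.X, Y)
    return ObjectiveValue(S=S, rss=weighted_rss(dataset.X, dataset.dX, Y, S))
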