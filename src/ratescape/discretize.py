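"""Bin layout and lag-time transition counting.

The sampling range ``[v_lo, v_hi]`` is split into ``n`` equal interior bins;
two pseudo-bins, index 0 on the left and n+1 on the right, represent the
absorbing walls.  Transitions are counted over non-overlapping windows of a
lag time tau: the source bin is the fixed-grid bin of the window's first
sample, and the destination is found on a grid shifted so the window starts
at a bin centre — operationally, by rounding the displacement to an integer
number of bin widths.  This shifted-grid rule removes the discretisation
error that a fixed grid would introduce for steps starting off-centre.

Once a trajectory is absorbed it contributes nothing further; the window in
which it exits is recorded as a single transition into the corresponding
absorbing pseudo-bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .simulate import TrajectoryEnsemble

__all__ = ["Grid", "TransitionCounts", "assign_bin", "count_transitions"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Grid:
    """Equal-width interior bins 1..n plus absorbing pseudo-bins 0 and n+1."""

    n: int
    v_lo: float
    v_hi: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 interior bins")
        if not self.v_lo < self.v_hi:
            raise ValueError("v_lo must be < v_hi")

    @property
    def dv(self) -> float:
        return (self.v_hi - self.v_lo) / self.n

    @property
    def centers(self) -> np.ndarray:
        """Centres of interior bins j = 1..n."""
        return self.v_lo + (np.arange(1, self.n + 1) - 0.5) * self.dv

    @property
    def interior_edges(self) -> np.ndarray:
        """The n-1 edges between interior bins (where D is reported)."""
        return self.v_lo + np.arange(1, self.n) * self.dv

    @classmethod
    def centered(cls, center: float, width: float, n: int) -> "Grid":
        """Grid of ``n`` bins spanning ``width`` centred on ``center``."""
        return cls(n=n, v_lo=center - width / 2.0, v_hi=center + width / 2.0)


def assign_bin(v, grid: Grid):
    """Map coordinates to bin indices in {0, 1..n, n+1}.

    Interior bins are right-half-open, ``[edge_j, edge_{j+1})``; anything
    below ``v_lo`` maps to 0 and anything at or above ``v_hi`` to n+1.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("NaN coordinate in trajectory data")
    idx = 1 + np.floor((v - grid.v_lo) / grid.dv).astype(np.int64)
    idx = np.where(v < grid.v_lo, 0, idx)
    idx = np.where(v >= grid.v_hi, grid.n + 1, idx)
    idx = np.clip(idx, 0, grid.n + 1)
    return idx if idx.ndim else int(idx)


@dataclass(frozen=True)
class TransitionCounts:
    """(n+2)x(n+2) matrix of lag-tau transition counts.

    ``counts[i, j]`` is the number of observed j -> i transitions.  Columns
    0 and n+1 are identically zero: absorbed trajectories never leave the
    pseudo-bins.
    """

    counts: np.ndarray
    tau: float
    grid: Grid

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _windows_per_traj(n_samples: int, m: int) -> int:
    return (n_samples - 1) // m


def count_transitions(
    ensemble: TrajectoryEnsemble | Iterable, grid: Grid, tau: float
) -> TransitionCounts:
    """Count lag-``tau`` transitions of an ensemble on ``grid``.

    ``tau`` must be an integer multiple of the recording interval.  Windows
    are non-overlapping (stride tau) so that the counts are statistically
    independent, as the product likelihood assumes.  A trajectory that exits
    before completing its current window contributes one final transition
    from that window's source bin into the absorbing pseudo-bin on the side
    it left, and nothing afterwards.
    """
    trajs = list(ensemble)
    if not trajs:
        raise ValueError("empty trajectory ensemble")
    dt_rec = trajs[0].dt_record
    m_float = tau / dt_rec
    m = int(round(m_float))
    if m < 1 or abs(m_float - m) > 1e-9 * max(1.0, m):
        raise ConfigError(
            f"lag time tau={tau} ps is not an integer multiple of the "
            f"recording interval dt_record={dt_rec} ps"
        )

    n = grid.n
    counts = np.zeros((n + 2, n + 2), dtype=np.int64)
    for traj in trajs:
        vals = traj.values
        if traj.dt_record != dt_rec:
            raise ConfigError("trajectories with mixed recording intervals")
        anchors = vals[::m]
        src = anchors[:-1]
        dst = anchors[1:]
        if src.size:
            j = assign_bin(src, grid)
            j = np.clip(j, 1, n)  # sources are in-range by construction
            disp = np.rint((dst - src) / grid.dv).astype(np.int64)
            i = np.clip(j + disp, 0, n + 1)
            np.add.at(counts, (i, j), 1)
        if traj.exit in ("left", "right"):
            k_complete = _windows_per_traj(len(vals), m)
            j_exit = int(np.clip(assign_bin(vals[k_complete * m], grid), 1, n))
            i_exit = 0 if traj.exit == "left" else n + 1
            counts[i_exit, j_exit] += 1
    return TransitionCounts(counts=counts, tau=float(tau), grid=grid)
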