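"""Sampled trajectory container shared by all models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConcentrationProfile"]


@dataclass(frozen=True)
class ConcentrationProfile:
    """A ``(t, x, y, cycle, phase)`` trajectory sampled on a time grid.

    ``y`` (amount awaiting absorption) is absent for bolus dosing; ``phase``
    ("assimilation"/"clearance") is present only for finite-absorption-time
    models.
    """

    t: np.ndarray
    x: np.ndarray
    cycle: np.ndarray
    y: np.ndarray | None = None
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "cycle", "y", "phase"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        """Columns ``t, x[, y], cycle[, phase]`` in that order."""
        cols: dict[str, np.ndarray] = {"t": self.t, "x": self.x}
        if self.y is not None:
            cols["y"] = self.y
        cols["cycle"] = self.cycle
        if self.phase is not None:
            cols["phase"] = self.phase
        return pd.DataFrame(cols)


def _check_grid(grid: np.ndarray, end_time: float) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1:
        raise ValueError("grid must be one-dimensional")
    if grid.size and np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    if grid.size and (grid[0] < 0 or grid[-1] > end_time):
        raise ValueError(f"grid must lie within [0, {end_time}]")
    return grid
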