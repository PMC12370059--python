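"""Uniform sampling grids for trajectory data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_POINTS = 481
DEFAULT_DT_MIN = 1.0


@dataclass(frozen=True)
class TimeGrid:
    """Uniformly spaced sampling grid in minutes, t = 0 at stimulation onset.

    The default grid has 481 points at 1-minute spacing, spanning 0-480 min
    (an 8-hour course).
    """

    n_points: int = DEFAULT_N_POINTS
    dt: float = DEFAULT_DT_MIN
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.t_start + self.dt * np.arange(self.n_points)

    @property
    def span(self) -> float:
        """Total covered duration (n_points - 1) * dt, minutes."""
        return (self.n_points - 1) * self.dt

    @property
    def t_end(self) -> float:
        return self.t_start + self.span


def default_grid() -> TimeGrid:
    return TimeGrid()


@dataclass(frozen=True)
class Trajectory:
    """One sampled activity time series with its stimulus/regime labels."""

    values: np.ndarray
    grid: TimeGrid
    ligand: str = ""
    ligand_dose: str = ""
    regime_id: str = "untreated"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("trajectory values must be one-dimensional")
        if len(values) != self.grid.n_points:
            raise ValueError(
                f"trajectory length {len(values)} does not match grid "
                f"n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory values must be finite")

    @property
    def stimulus(self) -> tuple[str, str]:
        return (self.ligand, self.ligand_dose)
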