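"""Grid simulation: full stimulus x regime trajectory sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from tempocode.sim_engine.grid import TimeGrid, Trajectory
from tempocode.sim_engine.inputs import input_function
from tempocode.sim_engine.model import find_steady_state, simulate_trajectory
from tempocode.sim_engine.params import (
    CoreModelParams,
    DrugRegime,
    LigandInputSpec,
    apply_regime,
)

SimulatorFn = Callable[[CoreModelParams, Callable[[float], float], TimeGrid], np.ndarray]


@dataclass
class TrajectorySet:
    """A complete grid of trajectories indexed by stimulus and regime.

    ``trajectories[regime_id][stimulus_label]`` holds one Trajectory; the
    grid is complete (every regime has every stimulus exactly once).
    """

    grid: TimeGrid
    stimulus_order: tuple[str, ...]
    regime_ids: tuple[str, ...]
    trajectories: dict[str, dict[str, Trajectory]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.trajectories.values())

    def regime_matrix(self, regime_id: str) -> np.ndarray:
        """Stimuli x timepoints matrix for one regime, canonical row order."""
        rows = [self.trajectories[regime_id][s].values for s in self.stimulus_order]
        return np.vstack(rows)

    def validate_complete(self) -> None:
        for rid in self.regime_ids:
            per = self.trajectories.get(rid)
            if per is None or set(per) != set(self.stimulus_order):
                raise ValueError(f"incomplete trajectory grid for regime {rid!r}")

    def to_tensor(
        self,
        ligands: Sequence[str],
        dose_levels: Sequence[str],
        drugs: Sequence[str],
        n_doses: int,
    ) -> np.ndarray:
        """Reshape single-drug regimes into a (I, J, K, L, T) tensor.

        Axes: ligand, ligand dose, drug, drug dose, time. Regime ids must
        follow the ``{drug}_DD{l}`` convention produced by the grid builder.
        """
        I, J, K, L = len(ligands), len(dose_levels), len(drugs), n_doses
        tensor = np.empty((I, J, K, L, self.grid.n_points))
        for i, ligand in enumerate(ligands):
            for j, dose in enumerate(dose_levels):
                label = f"{ligand}_{dose[0]}"
                for k, drug in enumerate(drugs):
                    for l in range(L):
                        rid = f"{drug}_DD{l + 1}"
                        tensor[i, j, k, l] = self.trajectories[rid][label].values
        return tensor


def simulate_regime(
    params: CoreModelParams,
    regime: DrugRegime,
    ligand_specs: Sequence[LigandInputSpec],
    grid: TimeGrid,
    simulator: SimulatorFn | None = None,
) -> dict[str, Trajectory]:
    """Simulate all stimuli under one regime, sharing the phase-1 steady state."""
    p = apply_regime(params, regime)
    out: dict[str, Trajectory] = {}
    if simulator is None:
        y0 = find_steady_state(p)
        for spec in ligand_specs:
            values = simulate_trajectory(p, input_function(spec, p), grid, y0=y0)
            out[spec.label] = Trajectory(
                values=values, grid=grid, ligand=spec.ligand,
                ligand_dose=spec.dose_level, regime_id=regime.regime_id,
            )
    else:
        for spec in ligand_specs:
            values = simulator(p, input_function(spec, p), grid)
            out[spec.label] = Trajectory(
                values=values, grid=grid, ligand=spec.ligand,
                ligand_dose=spec.dose_level, regime_id=regime.regime_id,
            )
    return out


def simulate_grid(
    params: CoreModelParams,
    regimes: Iterable[DrugRegime],
    ligand_specs: Sequence[LigandInputSpec],
    grid: TimeGrid,
    include_untreated: bool = True,
    simulator: SimulatorFn | None = None,
    progress: Callable[[str], None] | None = None,
) -> TrajectorySet:
    """Simulate the complete stimulus x regime grid, deterministically.

    The untreated 15-stimulus set is emitted under regime id ``untreated``
    unless disabled. A custom ``simulator`` callable may replace the bundled
    model (plug-in contract: ``(params, input_fn, grid) -> values``).
    """
    regimes = list(regimes)
    if include_untreated:
        regimes = [DrugRegime.untreated()] + regimes
    stimulus_order = tuple(spec.label for spec in ligand_specs)
    tset = TrajectorySet(
        grid=grid,
        stimulus_order=stimulus_order,
        regime_ids=tuple(r.regime_id for r in regimes),
    )
    for regime in regimes:
        tset.trajectories[regime.regime_id] = simulate_regime(
            params, regime, ligand_specs, grid, simulator=simulator
        )
        if progress is not None:
            progress(regime.regime_id)
    tset.validate_complete()
    return tset
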