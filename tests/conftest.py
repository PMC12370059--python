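"""Shared fixtures.

Expensive simulation fixtures are session-scoped and use a reduced 5-minute
sampling grid so the whole suite stays inside the CI budget; the grid span
(0-480 min) and the experimental design (15 stimuli x 200 regimes) are kept
at full scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from tempocode.clustering import Partition
from tempocode.codons import codon_table, normalize_codons
from tempocode.sim_engine import (
    DEFAULT_COMPOUNDS,
    DEFAULT_LIGAND_SPECS,
    TimeGrid,
    build_dose_ladder,
    default_model_params,
    simulate_grid,
    single_drug_regimes,
)

REDUCED_GRID = TimeGrid(n_points=97, dt=5.0)


@pytest.fixture(scope="session")
def reduced_grid() -> TimeGrid:
    return REDUCED_GRID


@pytest.fixture(scope="session")
def default_grid_full() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def model_params():
    return default_model_params()


@pytest.fixture(scope="session")
def ladder():
    return build_dose_ladder()


@pytest.fixture(scope="session")
def untreated_set(model_params, reduced_grid):
    """The untreated 15-stimulus set on the reduced grid."""
    return simulate_grid(
        model_params, [], DEFAULT_LIGAND_SPECS, reduced_grid,
        include_untreated=True,
    )


@pytest.fixture(scope="session")
def full_run(model_params, ladder, reduced_grid):
    """Complete single-drug grid (200 regimes + untreated) with codon tables."""
    regimes = single_drug_regimes(DEFAULT_COMPOUNDS, ladder)
    tset = simulate_grid(model_params, regimes, DEFAULT_LIGAND_SPECS, reduced_grid)
    trajs = [
        tset.trajectories[rid][label]
        for rid in tset.regime_ids
        for label in tset.stimulus_order
    ]
    table = codon_table(trajs)
    norm, bounds = normalize_codons(table)
    return {"tset": tset, "table": table, "norm": norm, "bounds": bounds}


def random_partition(rng: np.random.Generator, n: int, max_clusters: int) -> Partition:
    """Uniform-ish random partition of n labeled elements."""
    k = int(rng.integers(1, max_clusters + 1))
    assignment = rng.integers(0, k, size=n)
    # ensure every cluster id in use maps to a non-empty cluster
    ids = np.unique(assignment)
    clusters = [[f"e{i}" for i in np.nonzero(assignment == c)[0]] for c in ids]
    return Partition.from_lists(clusters)
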