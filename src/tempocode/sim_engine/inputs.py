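"""Upstream kinase forcing curves that stand in for receptor modules."""

from __future__ import annotations

from typing import Callable

import numpy as np

from tempocode.sim_engine.grid import TimeGrid
from tempocode.sim_engine.params import CoreModelParams, LigandInputSpec


def input_function(
    spec: LigandInputSpec,
    params: CoreModelParams | None = None,
) -> Callable[[float], float]:
    """Closed-form forcing u(t), vectorized over t (minutes since onset).

    ``params.input_decay`` scales the decay rate (multiplier < 1 slows decay,
    sustaining the input) and ``params.input_plateau`` exponentiates the
    plateau fraction (exponent < 1 raises the sustained late phase), so that
    compounds acting upstream of the core module are expressible as parameter
    multipliers.
    """
    amplitude = spec.amplitude
    rise = spec.rise_time
    decay_scale = params.input_decay if params is not None else 1.0
    plateau_pow = params.input_plateau if params is not None else 1.0
    decay_rate = decay_scale / spec.decay_time
    plateau = spec.plateau_fraction ** plateau_pow if spec.plateau_fraction > 0 else (
        1.0 if plateau_pow == 0 else 0.0
    )

    def u(t):
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        envelope = 1.0 - np.exp(-t / rise)
        late = plateau + (1.0 - plateau) * np.exp(-decay_rate * t)
        return amplitude * envelope * late

    return u


def ikk_input_curve(
    spec: LigandInputSpec,
    grid: TimeGrid,
    params: CoreModelParams | None = None,
) -> np.ndarray:
    """Sample the forcing curve on the grid. Non-negative, zero at t = 0."""
    return input_function(spec, params)(grid.times - grid.t_start)
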