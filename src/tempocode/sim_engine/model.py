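"""Bundled minimal negative-feedback core model and two-phase simulation.

The model tracks five states: inhibitor mRNA (m), free cytoplasmic inhibitor
protein (I), nuclear transcription factor (Nn), free cytoplasmic transcription
factor (Nc), and the cytoplasmic inhibitor:TF complex (C). Kinase activity is
an external forcing: IKK(t) = ikk_basal + ikk_gain * u(t).

Mass-action reactions::

    dm/dt  = txn_basal + txn_induced * (Nn / total)**2 - mrna_decay * m
    dI/dt  = translation * m - nuc_export * I * Nn
             - (ideg_basal + ideg_ikk * IKK) * I
    dNn/dt = nuc_import * Nc - nuc_export * I * Nn
    dNc/dt = (cdeg_basal + cdeg_ikk * IKK) * C - nuc_import * Nc
    dC/dt  = nuc_export * I * Nn - (cdeg_basal + cdeg_ikk * IKK) * C

The TF pools satisfy d(Nn + Nc + C)/dt = 0, so total TF is structurally
conserved; the integrator is still checked against drift. Simulation runs in
two phases: pre-equilibration with zero stimulus to a steady state, then the
stimulated course sampled exactly on the output grid.

Any callable with the signature ``(params, input_fn, grid) -> np.ndarray`` can
replace :func:`simulate_trajectory` downstream, so a full published model can
be plugged in behind the same interface.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from tempocode.sim_engine.grid import TimeGrid, Trajectory
from tempocode.sim_engine.params import CoreModelParams

RTOL = 1e-6
ATOL = 1e-9
STEADY_STATE_TOL = 1e-8
STEADY_STATE_BLOCK_MIN = 5000.0
STEADY_STATE_MAX_MIN = 1e6
CONSERVATION_RTOL = 1e-6


class SimulationError(RuntimeError):
    """Integration failure or non-convergence of the pre-equilibration phase."""


def _rhs_factory(p: CoreModelParams, input_fn: Callable[[float], float]):
    total = p.nfkb_total

    def rhs(t, y):
        m, I, Nn, Nc, C = y
        ikk = p.ikk_basal + p.ikk_gain * input_fn(t)
        capture = p.nuc_export * I * Nn
        release = (p.cdeg_basal + p.cdeg_ikk * ikk) * C
        dm = (p.txn_basal + p.txn_induced * (Nn / total) ** 2
              - (p.mrna_decay + p.dilution) * m)
        dI = (p.translation * m - capture
              - (p.ideg_basal + p.ideg_ikk * ikk + p.dilution) * I)
        dNn = p.nuc_import * Nc - capture
        dNc = release - p.nuc_import * Nc
        dC = capture - release
        return (dm, dI, dNn, dNc, dC)

    return rhs


def _zero_input(t):
    return 0.0


def find_steady_state(params: CoreModelParams) -> np.ndarray:
    """Phase-1 pre-equilibration: integrate with zero stimulus to a fixed point.

    Integrates in blocks until two successive block endpoints differ by less
    than STEADY_STATE_TOL in max-norm; raises SimulationError if the cap on
    simulated time is exceeded.
    """
    rhs = _rhs_factory(params, _zero_input)
    total = params.nfkb_total
    # start with everything complexed: the resting configuration
    y = np.array([params.txn_basal / max(params.mrna_decay, 1e-12),
                  0.01 * total, 0.0, 0.0, total])
    elapsed = 0.0
    while elapsed < STEADY_STATE_MAX_MIN:
        sol = solve_ivp(
            rhs, (0.0, STEADY_STATE_BLOCK_MIN), y,
            method="LSODA", rtol=RTOL, atol=ATOL,
        )
        if not sol.success:
            raise SimulationError(
                f"phase-1 integration failed: {sol.message} (params={params.as_dict()})"
            )
        y_new = sol.y[:, -1]
        elapsed += STEADY_STATE_BLOCK_MIN
        change = float(np.max(np.abs(y_new - y)))
        if change < STEADY_STATE_TOL:
            return np.maximum(y_new, 0.0)
        y = y_new
    raise SimulationError(
        f"phase-1 did not reach steady state within {STEADY_STATE_MAX_MIN} min "
        f"(last max-norm change {change:.3e})"
    )


def simulate_trajectory(
    params: CoreModelParams,
    input_fn: Callable[[float], float],
    grid: TimeGrid,
    y0: np.ndarray | None = None,
    return_states: bool = False,
):
    """Two-phase simulation; returns nuclear TF activity sampled on the grid.

    ``y0`` may carry a pre-computed phase-1 steady state (it depends only on
    the parameters, so grids over many stimuli can share it). With
    ``return_states`` the full state matrix (5 x n_points) is returned too.
    """
    if y0 is None:
        y0 = find_steady_state(params)
    rhs = _rhs_factory(params, input_fn)
    t_rel = grid.times - grid.t_start
    sol = solve_ivp(
        rhs, (t_rel[0], t_rel[-1]), y0,
        method="LSODA", t_eval=t_rel, rtol=RTOL, atol=ATOL,
    )
    if not sol.success:
        raise SimulationError(f"phase-2 integration failed: {sol.message}")
    states = sol.y
    pools = states[2] + states[3] + states[4]
    drift = np.max(np.abs(pools - params.nfkb_total)) / params.nfkb_total
    if drift > CONSERVATION_RTOL:
        raise SimulationError(
            f"total TF conservation violated: relative drift {drift:.3e}"
        )
    nuclear = np.clip(states[2], 0.0, None)
    if return_states:
        return nuclear, states
    return nuclear
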