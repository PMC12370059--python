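"""Six-feature ("signaling codon") extraction from sampled trajectories.

For a trajectory x_1..x_N sampled at interval dt (minutes):

* ``speed``    — time of the first local maximum (x_i > x_{i-1}, x_i >= x_{i+1},
  x_i > 0) with 1-based index i > 3, reported as (i - 1) * dt; sentinel
  (N - 1) * dt if no such maximum exists.
* ``peak``     — max over samples.
* ``duration`` — count of samples strictly above a low threshold, times dt.
* ``auc``      — trapezoidal integral over the grid.
* ``evl``      — time at which the cumulative trapezoidal integral first best
  approximates half the total (ties to the earliest index).
* ``osc``      — summed discrete-Fourier power over frequencies in
  [0.33, 1] per hour (endpoints inclusive, positive frequencies only).

Trajectories whose peak falls strictly below the non-responder cutoff are
flagged non-responders; their speed and evl are replaced by the grid span so
that non-responders sit far from fast/early responders in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from tempocode.sim_engine.grid import Trajectory

DEFAULT_THRESHOLD = 0.05
DEFAULT_NONRESPONDER_CUTOFF = 0.05
OSC_BAND_PER_HOUR = (0.33, 1.0)

#: Canonical column order for codon vectors and tables.
CODON_NAMES = ("speed", "peak", "duration", "auc", "evl", "osc")

# 1-based first-peak indices must exceed 3, i.e. 0-based index >= 3
_MIN_PEAK_INDEX = 3


@dataclass(frozen=True)
class CodonVector:
    speed: float
    peak: float
    duration: float
    auc: float
    evl: float
    osc: float
    is_nonresponder: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CODON_NAMES])


def speed(traj: Trajectory) -> float:
    """Time of the first qualifying local maximum; grid span if none."""
    x = traj.values
    if len(x) < 5:
        raise ValueError("speed requires at least 5 samples")
    interior = np.arange(1, len(x) - 1)
    is_peak = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & (x[1:-1] > 0)
    candidates = interior[is_peak & (interior >= _MIN_PEAK_INDEX)]
    if len(candidates) == 0:
        return traj.grid.span
    return float(candidates[0]) * traj.grid.dt


def peak(traj: Trajectory) -> float:
    return float(np.max(traj.values))


def duration(traj: Trajectory, threshold: float = DEFAULT_THRESHOLD) -> float:
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return float(np.count_nonzero(traj.values > threshold)) * traj.grid.dt


def auc(traj: Trajectory) -> float:
    return float(np.trapezoid(traj.values, dx=traj.grid.dt))


def evl(traj: Trajectory) -> float:
    """Half-area time: earliest grid point whose cumulative integral is
    closest to half the total."""
    cum = cumulative_trapezoid(traj.values, dx=traj.grid.dt, initial=0.0)
    half = 0.5 * np.max(cum)
    idx = int(np.argmin(np.abs(cum - half)))  # argmin takes the first minimum
    return idx * traj.grid.dt


def osc(traj: Trajectory) -> float:
    """Band power of the discrete spectrum, 0.33-1 per hour inclusive."""
    x = traj.values
    dt_hours = traj.grid.dt / 60.0
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=dt_hours)
    in_band = (freqs >= OSC_BAND_PER_HOUR[0]) & (freqs <= OSC_BAND_PER_HOUR[1])
    in_band[0] = False  # DC is never in band
    return float(np.sum(np.abs(spectrum[in_band]) ** 2))


def extract_codons(
    traj: Trajectory,
    threshold: float = DEFAULT_THRESHOLD,
    nonresponder_cutoff: float = DEFAULT_NONRESPONDER_CUTOFF,
) -> CodonVector:
    """Assemble the six codons, applying the non-responder correction."""
    pk = peak(traj)
    nonresp = pk < nonresponder_cutoff  # strictly below the cutoff
    span = traj.grid.span
    return CodonVector(
        speed=span if nonresp else speed(traj),
        peak=pk,
        duration=duration(traj, threshold),
        auc=auc(traj),
        evl=span if nonresp else evl(traj),
        osc=osc(traj),
        is_nonresponder=nonresp,
    )


def codon_table(
    trajectories,
    threshold: float = DEFAULT_THRESHOLD,
    nonresponder_cutoff: float = DEFAULT_NONRESPONDER_CUTOFF,
) -> pd.DataFrame:
    """Codon table for an iterable of trajectories.

    Columns: regime_id, ligand, ligand_dose, the six codons, is_nonresponder.
    """
    records = []
    for traj in trajectories:
        vec = extract_codons(traj, threshold, nonresponder_cutoff)
        records.append(
            {
                "regime_id": traj.regime_id,
                "ligand": traj.ligand,
                "ligand_dose": traj.ligand_dose,
                **{name: getattr(vec, name) for name in CODON_NAMES},
                "is_nonresponder": vec.is_nonresponder,
            }
        )
    return pd.DataFrame.from_records(records)


def normalize_codons(
    table: pd.DataFrame,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-codon min-max scaling to [0, 1] over the whole collection.

    Bounds are computed jointly across all regimes in ``table`` (so distances
    are comparable across regimes) unless explicitly supplied. Constant
    columns map to 0. Returns the normalized table and the bounds used.
    """
    out = table.copy()
    if bounds is None:
        bounds = {
            name: (float(table[name].min()), float(table[name].max()))
            for name in CODON_NAMES
        }
    for name in CODON_NAMES:
        lo, hi = bounds[name]
        if hi > lo:
            out[name] = (table[name] - lo) / (hi - lo)
        else:
            out[name] = 0.0
    return out, bounds
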