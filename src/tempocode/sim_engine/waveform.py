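"""Parametric waveform generator with analytically known dynamic features.

Waveforms are damped, optionally oscillating pulses::

    w(t) = A * (1 - exp(-(t-t0)/tau_r)) * exp(-k_d (t-t0)) * (1 - d cos(omega (t-t0)))

for t >= onset t0 (zero before), with oscillation depth d in [0, 1] so the
curve never needs clipping. Because every term is a product of exponentials
and cosines, the integral, cumulative integral, and derivative have closed
forms; the expected values of the six dynamic features are computed from
those continuous-time definitions, independently of the discrete extraction
code, and returned alongside the sampled trajectory for use as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from tempocode.sim_engine.grid import TimeGrid, Trajectory

_OVERSAMPLE = 50  # fine-grid factor for locating continuous-time extrema


@dataclass(frozen=True)
class WaveformSpec:
    amplitude: float
    onset: float = 0.0          # minutes
    rise_time: float = 10.0     # minutes
    decay_rate: float = 0.005   # per minute
    osc_freq: float = 0.0       # per hour
    osc_depth: float = 0.0      # in [0, 1]

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.osc_freq < 0:
            raise ValueError("osc_freq must be >= 0")
        if not 0.0 <= self.osc_depth <= 1.0:
            raise ValueError("osc_depth must be in [0, 1]")
        if self.rise_time <= 0:
            raise ValueError("rise_time must be > 0")

    @property
    def omega(self) -> float:
        """Angular frequency, radians per minute."""
        return 2.0 * np.pi * self.osc_freq / 60.0


def waveform_values(spec: WaveformSpec, t: np.ndarray) -> np.ndarray:
    """Evaluate the continuous waveform at times ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    s = np.maximum(t - spec.onset, 0.0)
    active = t >= spec.onset
    env = (1.0 - np.exp(-s / spec.rise_time)) * np.exp(-spec.decay_rate * s)
    osc = 1.0 - spec.osc_depth * np.cos(spec.omega * s)
    return np.where(active, np.clip(spec.amplitude * env * osc, 0.0, None), 0.0)


def _exp_integral(a: float, tau: float) -> float:
    """Integral of exp(-a t) over [0, tau]."""
    if a == 0.0:
        return tau
    return (1.0 - np.exp(-a * tau)) / a


def _exp_cos_integral(a: float, b: float, tau: float) -> float:
    """Integral of exp(-a t) cos(b t) over [0, tau]."""
    if b == 0.0:
        return _exp_integral(a, tau)
    denom = a * a + b * b
    return (a - np.exp(-a * tau) * (a * np.cos(b * tau) - b * np.sin(b * tau))) / denom


def cumulative_integral(spec: WaveformSpec, tau: float) -> float:
    """Closed-form integral of the waveform over [onset, onset + tau]."""
    if tau <= 0 or spec.amplitude == 0:
        return 0.0
    kd = spec.decay_rate
    beta = kd + 1.0 / spec.rise_time
    w = spec.omega
    d = spec.osc_depth
    base = _exp_integral(kd, tau) - _exp_integral(beta, tau)
    if d == 0.0 or w == 0.0:
        osc_part = 0.0 if d == 0.0 else d * base
    else:
        osc_part = d * (_exp_cos_integral(kd, w, tau) - _exp_cos_integral(beta, w, tau))
    return spec.amplitude * (base - osc_part)


def _fine_times(spec: WaveformSpec, grid: TimeGrid) -> np.ndarray:
    n_fine = (grid.n_points - 1) * _OVERSAMPLE + 1
    return np.linspace(grid.t_start, grid.t_end, n_fine)


def expected_codons(
    spec: WaveformSpec,
    grid: TimeGrid,
    threshold: float = 0.05,
    nonresponder_cutoff: float = 0.05,
) -> dict[str, float]:
    """Continuous-time expected values of the six dynamic features.

    Peak and first-peak time come from an oversampled continuous search,
    AUC and the half-area time from the closed-form cumulative integral, and
    duration from root-located threshold crossings. The oscillatory-power
    entry is the band power of the discrete spectrum computed with a direct
    (naive) Fourier sum, independent of any FFT code path.
    """
    span = grid.span
    tail = span - (spec.onset - grid.t_start)
    out: dict[str, float] = {}

    fine = _fine_times(spec, grid)
    w_fine = waveform_values(spec, fine)

    peak_val = float(np.max(w_fine))
    out["peak"] = peak_val
    nonresp = peak_val < nonresponder_cutoff
    out["is_nonresponder"] = nonresp

    total = cumulative_integral(spec, tail)
    out["auc"] = total

    # first continuous local maximum (positive value), via derivative sign change
    out["speed"] = span if nonresp else _first_peak_time(fine, w_fine, grid)

    if nonresp:
        out["evl"] = span
    elif total > 0:
        half = 0.5 * total
        f = lambda tau: cumulative_integral(spec, tau) - half
        tau_half = brentq(f, 0.0, tail, xtol=1e-10)
        out["evl"] = spec.onset - grid.t_start + tau_half
    else:
        out["evl"] = 0.0

    out["duration"] = _measure_above(fine, w_fine, spec, threshold)
    out["osc"] = _band_power_naive(
        waveform_values(spec, grid.times), grid.dt / 60.0
    )
    return out


def _first_peak_time(fine: np.ndarray, w_fine: np.ndarray, grid: TimeGrid) -> float:
    dw = np.diff(w_fine)
    rising = dw[:-1] > 0
    falling = dw[1:] <= 0
    positive = w_fine[1:-1] > 0
    idx = np.nonzero(rising & falling & positive)[0]
    if len(idx) == 0:
        return grid.span
    return float(fine[idx[0] + 1] - grid.t_start)


def _measure_above(
    fine: np.ndarray, w_fine: np.ndarray, spec: WaveformSpec, threshold: float
) -> float:
    """Lebesgue measure of {t : w(t) > threshold}, via refined crossings."""
    above = w_fine > threshold
    if not above.any():
        return 0.0
    g = lambda t: float(waveform_values(spec, np.array([t]))[0]) - threshold
    changes = np.nonzero(np.diff(above.astype(int)))[0]
    crossings = [brentq(g, fine[i], fine[i + 1], xtol=1e-10) for i in changes]
    bounds = []
    if above[0]:
        bounds.append(fine[0])
    bounds.extend(crossings)
    if above[-1]:
        bounds.append(fine[-1])
    total = 0.0
    for lo, hi in zip(bounds[::2], bounds[1::2]):
        total += hi - lo
    return total


def _band_power_naive(
    x: np.ndarray, dt_hours: float, band: tuple[float, float] = (0.33, 1.0)
) -> float:
    """Direct DFT band power (no FFT), positive frequencies in [band] per hour."""
    n = len(x)
    freqs = np.arange(1, n // 2 + 1) / (n * dt_hours)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    power = 0.0
    t_idx = np.arange(n)
    for k in np.arange(1, n // 2 + 1)[in_band]:
        coeff = np.sum(x * np.exp(-2j * np.pi * k * t_idx / n))
        power += abs(coeff) ** 2
    return float(power)


def generate_waveform(
    spec: WaveformSpec,
    grid: TimeGrid,
    threshold: float = 0.05,
    nonresponder_cutoff: float = 0.05,
) -> tuple[Trajectory, dict[str, float]]:
    """Sample the waveform on the grid and return it with its expected features."""
    values = waveform_values(spec, grid.times)
    traj = Trajectory(values=values, grid=grid, regime_id="waveform",
                      meta={"spec": spec})
    return traj, expected_codons(spec, grid, threshold, nonresponder_cutoff)


def triangle_pulse(
    grid: TimeGrid, center: float, half_width: float, amplitude: float
) -> Trajectory:
    """Symmetric triangular pulse; its features have simple exact values."""
    t = grid.times
    values = np.clip(amplitude * (1.0 - np.abs(t - center) / half_width), 0.0, None)
    return Trajectory(values=values, grid=grid, regime_id="triangle")
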