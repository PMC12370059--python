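"""Dose ladders and drug-regime enumeration."""

from __future__ import annotations

from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np

from tempocode.sim_engine.params import ConfigError, DrugRegime

DEFAULT_LADDER_STEPS = 20
DEFAULT_EXP_START = -0.15
DEFAULT_EXP_STOP = -3.0


def build_dose_ladder(
    n_steps: int = DEFAULT_LADDER_STEPS,
    exp_start: float = DEFAULT_EXP_START,
    exp_stop: float = DEFAULT_EXP_STOP,
) -> np.ndarray:
    """Multipliers 10**e for e linearly spaced from exp_start to exp_stop.

    The default ladder covers dose indices DD1..DD20 with multipliers from
    10**-0.15 down to 10**-3.
    """
    if n_steps < 1:
        raise ConfigError(f"n_steps must be >= 1, got {n_steps}")
    if not (np.isfinite(exp_start) and np.isfinite(exp_stop)):
        raise ConfigError("ladder exponents must be finite")
    exponents = np.linspace(exp_start, exp_stop, n_steps)
    return np.power(10.0, exponents)


def make_regime(
    compound: str,
    dd: int,
    targets: Sequence[str],
    ladder: np.ndarray,
) -> DrugRegime:
    """Single-compound regime at 1-based dose index ``dd``."""
    if not 1 <= dd <= len(ladder):
        raise ConfigError(
            f"dose index {dd} out of range 1..{len(ladder)} for {compound!r}"
        )
    mult = float(ladder[dd - 1])
    return DrugRegime(
        regime_id=f"{compound}_DD{dd}",
        components=((compound, dd),),
        multiplier_map={name: mult for name in targets},
    )


def single_drug_regimes(
    compounds: Mapping[str, Sequence[str]],
    ladder: np.ndarray,
) -> list[DrugRegime]:
    """All compounds at all ladder steps (10 compounds x 20 doses = 200)."""
    return [
        make_regime(compound, dd, targets, ladder)
        for compound, targets in compounds.items()
        for dd in range(1, len(ladder) + 1)
    ]


def combination_regimes(
    compounds: Mapping[str, Sequence[str]],
    ladder: np.ndarray,
    dose_indices: Iterable[int] = (5, 10),
) -> list[DrugRegime]:
    """Pairwise compound combinations at the given dose indices.

    For 10 compounds at 2 dose levels this yields C(10,2) x 2 x 2 = 180
    regimes; per-parameter multipliers compose multiplicatively.
    """
    dose_indices = list(dose_indices)
    regimes = []
    for (c1, c2) in combinations(compounds, 2):
        for d1, d2 in product(dose_indices, dose_indices):
            r1 = make_regime(c1, d1, compounds[c1], ladder)
            r2 = make_regime(c2, d2, compounds[c2], ladder)
            regimes.append(r1.combine(r2))
    return regimes
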