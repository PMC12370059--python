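"""Model parameters, ligand input specifications, and drug regimes."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


class ConfigError(ValueError):
    """Raised for invalid configuration values (unknown keys, bad ranges)."""


@dataclass(frozen=True)
class CoreModelParams:
    """Rate constants of the bundled minimal negative-feedback core model.

    All rates are per minute; concentrations are in arbitrary units (a.u.).
    ``input_decay`` and ``input_plateau`` shape the upstream kinase forcing
    curve rather than the core ODEs, so that compounds acting upstream of the
    core module can be expressed as parameter multipliers too.
    """

    ikk_gain: float = 1.0          # scales stimulus-driven kinase activity
    ikk_basal: float = 0.003       # resting kinase activity
    txn_basal: float = 5e-4        # constitutive inhibitor-mRNA transcription
    txn_induced: float = 0.10      # activity-induced transcription (Hill, n=2)
    translation: float = 0.50      # inhibitor protein synthesis per mRNA
    mrna_decay: float = 0.030
    ideg_basal: float = 0.005      # free-inhibitor basal degradation
    ideg_ikk: float = 0.40         # free-inhibitor kinase-dependent degradation
    cdeg_basal: float = 1e-4       # complexed-inhibitor basal degradation
    cdeg_ikk: float = 1.20         # complexed-inhibitor kinase-dependent degradation
    nuc_import: float = 0.50       # free TF nuclear import
    nuc_export: float = 5.0        # inhibitor-mediated nuclear capture/export
    input_decay: float = 1.0       # multiplier on the forcing-curve decay rate
    input_plateau: float = 1.0     # exponent on the forcing-curve plateau fraction
    dilution: float = 2e-4         # growth dilution of mRNA and free inhibitor;
                                   # not drug-targeted, bounds equilibration time
    nfkb_total: float = 1.0        # conserved total TF abundance

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigError(f"parameter {f.name!r} must be >= 0, got {v}")
        if self.nfkb_total <= 0:
            raise ConfigError(f"nfkb_total must be > 0, got {self.nfkb_total}")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_updates(self, **updates: float) -> "CoreModelParams":
        unknown = set(updates) - set(self.names())
        if unknown:
            raise ConfigError(f"unknown model parameter(s): {sorted(unknown)}")
        return replace(self, **updates)


@dataclass(frozen=True)
class LigandInputSpec:
    """Parametric upstream kinase activity curve for one ligand-dose condition.

    The curve is amplitude * (1 - exp(-t/rise_time)) * (p + (1-p) * exp(-t/decay_time))
    with p = plateau_fraction: it is zero at onset, rises with characteristic
    time ``rise_time`` and decays toward a sustained late phase.
    """

    ligand: str
    dose_level: str
    amplitude: float
    rise_time: float
    decay_time: float
    plateau_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ConfigError(
                f"amplitude must be in [0, 1], got {self.amplitude} "
                f"({self.ligand} {self.dose_level})"
            )
        if self.rise_time <= 0:
            raise ConfigError(f"rise_time must be > 0, got {self.rise_time}")
        if self.decay_time <= 0:
            raise ConfigError(f"decay_time must be > 0, got {self.decay_time}")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ConfigError(
                f"plateau_fraction must be in [0, 1], got {self.plateau_fraction}"
            )

    @property
    def label(self) -> str:
        return f"{self.ligand}_{self.dose_level[0]}"


@dataclass(frozen=True)
class DrugRegime:
    """A named set of parameter multipliers at one (or two) dose indices.

    ``components`` lists (compound, dose index) pairs; combination regimes
    compose their per-parameter multipliers multiplicatively.
    """

    regime_id: str
    components: tuple[tuple[str, int], ...]
    multiplier_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mult in self.multiplier_map.items():
            if not mult > 0:
                raise ConfigError(
                    f"multiplier for {name!r} in regime {self.regime_id!r} "
                    f"must be > 0, got {mult}"
                )

    @classmethod
    def untreated(cls) -> "DrugRegime":
        return cls(regime_id="untreated", components=(), multiplier_map={})

    def combine(self, other: "DrugRegime") -> "DrugRegime":
        """Multiplicative composition of two regimes' multiplier maps."""
        merged = dict(self.multiplier_map)
        for name, mult in other.multiplier_map.items():
            merged[name] = merged.get(name, 1.0) * mult
        return DrugRegime(
            regime_id=f"{self.regime_id}+{other.regime_id}",
            components=self.components + other.components,
            multiplier_map=merged,
        )


def apply_regime(params: CoreModelParams, regime: DrugRegime) -> CoreModelParams:
    """Return a copy of ``params`` with each targeted parameter multiplied.

    Raises ConfigError naming the offending key if the regime targets a
    parameter that does not exist on the model.
    """
    known = set(params.names())
    updates = {}
    for name, mult in regime.multiplier_map.items():
        if name not in known:
            raise ConfigError(
                f"regime {regime.regime_id!r} targets unknown parameter {name!r}"
            )
        updates[name] = getattr(params, name) * mult
    return params.with_updates(**updates) if updates else params
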