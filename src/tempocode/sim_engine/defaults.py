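"""Bundled default experimental design: ligand library and compound maps.

The 15-stimulus ligand library is calibrated qualitatively: five ligands at
three doses each, with dose-graded amplitude and duration, a complete
non-responder at the lowest LPS dose, and near-coincident responses for
high-dose CpG and high-dose Pam3CSK. The ten-compound library maps each
compound onto parameters of the bundled minimal model; the parameter indices
of the full published receptor-module model are carried as metadata so that
users substituting their own model can re-target the same compounds.
"""

from __future__ import annotations

from tempocode.sim_engine.params import CoreModelParams, LigandInputSpec

LIGANDS = ("TNF", "LPS", "CpG", "PolyIC", "Pam3CSK")
DOSE_LEVELS = ("Low", "Medium", "High")

#: Canonical stimulus order: TNF L/M/H, LPS L/M/H, CpG L/M/H, PolyIC L/M/H,
#: Pam3CSK L/M/H.
STIMULUS_ORDER = tuple(
    f"{ligand}_{dose[0]}" for ligand in LIGANDS for dose in DOSE_LEVELS
)

#: Index (0-based) of the untreated non-responder condition (low-dose LPS).
NONRESPONDER_STIMULUS = "LPS_L"

DEFAULT_LIGAND_SPECS = (
    # TNF: fast onset, transient-to-sustained with dose; oscillatory via feedback
    LigandInputSpec("TNF", "Low", amplitude=0.30, rise_time=4.0,
                    decay_time=35.0, plateau_fraction=0.02),
    LigandInputSpec("TNF", "Medium", amplitude=0.55, rise_time=4.0,
                    decay_time=55.0, plateau_fraction=0.10),
    LigandInputSpec("TNF", "High", amplitude=0.75, rise_time=4.0,
                    decay_time=80.0, plateau_fraction=0.30),
    # LPS: lowest dose is a complete non-responder
    LigandInputSpec("LPS", "Low", amplitude=0.01, rise_time=20.0,
                    decay_time=120.0, plateau_fraction=0.40),
    LigandInputSpec("LPS", "Medium", amplitude=0.35, rise_time=18.0,
                    decay_time=140.0, plateau_fraction=0.45),
    LigandInputSpec("LPS", "High", amplitude=0.60, rise_time=15.0,
                    decay_time=160.0, plateau_fraction=0.55),
    # CpG: slow-ish rise, sustained
    LigandInputSpec("CpG", "Low", amplitude=0.15, rise_time=30.0,
                    decay_time=180.0, plateau_fraction=0.35),
    LigandInputSpec("CpG", "Medium", amplitude=0.38, rise_time=28.0,
                    decay_time=190.0, plateau_fraction=0.45),
    LigandInputSpec("CpG", "High", amplitude=0.58, rise_time=25.0,
                    decay_time=200.0, plateau_fraction=0.50),
    # PolyIC: dose mostly shifts activation speed
    LigandInputSpec("PolyIC", "Low", amplitude=0.25, rise_time=110.0,
                    decay_time=240.0, plateau_fraction=0.55),
    LigandInputSpec("PolyIC", "Medium", amplitude=0.42, rise_time=80.0,
                    decay_time=240.0, plateau_fraction=0.55),
    LigandInputSpec("PolyIC", "High", amplitude=0.60, rise_time=55.0,
                    decay_time=240.0, plateau_fraction=0.55),
    # Pam3CSK: low-amplitude oscillatory to high sustained; high dose tracks CpG high
    LigandInputSpec("Pam3CSK", "Low", amplitude=0.12, rise_time=12.0,
                    decay_time=90.0, plateau_fraction=0.10),
    LigandInputSpec("Pam3CSK", "Medium", amplitude=0.33, rise_time=18.0,
                    decay_time=150.0, plateau_fraction=0.35),
    LigandInputSpec("Pam3CSK", "High", amplitude=0.57, rise_time=24.0,
                    decay_time=200.0, plateau_fraction=0.50),
)

#: Compound -> bundled-model parameters scaled by the dose-ladder multiplier.
DEFAULT_COMPOUNDS: dict[str, tuple[str, ...]] = {
    "IKKi": ("ikk_gain", "ideg_ikk", "cdeg_ikk"),
    "TAK1i": ("ikk_gain",),
    "BTRCPi": ("ideg_ikk", "cdeg_ikk"),
    "MG132": ("ideg_ikk", "ideg_basal", "cdeg_ikk", "cdeg_basal"),
    "PP2Ai": ("input_decay",),
    "TSA": ("txn_basal",),
    "PDTC": ("txn_induced",),
    "CHX": ("translation",),
    "Sel": ("nuc_export",),
    "CHL": ("input_plateau",),
}

#: Kinetic-parameter indices of the full published receptor-module model
#: targeted by each compound; metadata only, for users plugging in that model.
FULL_MODEL_PARAMETER_TABLE: dict[str, tuple[str, ...]] = {
    "IKKi": ("k3", "k25", "k26"),
    "TAK1i": ("k67",),
    "BTRCPi": ("k25", "k26"),
    "PP2Ai": ("k4",),
    "TSA": ("k5",),
    "PDTC": ("k6",),
    "CHX": ("k8",),
    "Sel": ("k11", "k12", "k14"),
    "MG132": ("k15", "k16", "k26", "k53", "k58", "k61", "k64", "k69", "k73", "k75"),
    "CHL": ("k30", "k42", "k43", "k44", "k78", "k83", "k86", "k87", "k92", "k93"),
}

#: Regimes used for epsilon calibration against the bundled expert partitions.
CALIBRATION_REGIMES = ("CHL_DD8", "IKKi_DD11", "MG132_DD6", "Sel_DD15", "TAK1i_DD14")


def default_model_params() -> CoreModelParams:
    return CoreModelParams()
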