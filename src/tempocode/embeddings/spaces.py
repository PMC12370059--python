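"""Feature matrices: the 15 stimuli of one regime in each comparison space."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tempocode.codons import CODON_NAMES
from tempocode.embeddings.cpd import CPDModel
from tempocode.embeddings.fpca import FPCAModel
from tempocode.sim_engine.defaults import DOSE_LEVELS, LIGANDS
from tempocode.sim_engine.gridsim import TrajectorySet

SPACE_LABELS = ("trajectory", "cpd7", "cpd40", "fpca5", "codon")


class MissingModelError(RuntimeError):
    """The requested space needs a fitted model that was not provided."""


@dataclass(frozen=True)
class FeatureMatrix:
    space: str
    regime_id: str
    values: np.ndarray               # 15 x n_features, canonical row order
    stimulus_order: tuple[str, ...]
    nonresponders: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")


def trajectory_features(tset: TrajectorySet, regime_id: str) -> FeatureMatrix:
    return FeatureMatrix(
        space="trajectory",
        regime_id=regime_id,
        values=tset.regime_matrix(regime_id),
        stimulus_order=tset.stimulus_order,
    )


def codon_features(
    norm_table: pd.DataFrame, regime_id: str, stimulus_order: tuple[str, ...]
) -> FeatureMatrix:
    """15 x 6 matrix of normalized codons for one regime."""
    sub = norm_table[norm_table["regime_id"] == regime_id].copy()
    sub["label"] = sub["ligand"] + "_" + sub["ligand_dose"].str[0]
    sub = sub.set_index("label").reindex(list(stimulus_order))
    if sub[list(CODON_NAMES)].isna().any().any():
        missing = sub[sub[list(CODON_NAMES)].isna().any(axis=1)].index.tolist()
        raise MissingModelError(
            f"regime {regime_id!r} is missing stimuli {missing} in the codon table"
        )
    return FeatureMatrix(
        space="codon",
        regime_id=regime_id,
        values=sub[list(CODON_NAMES)].to_numpy(dtype=float),
        stimulus_order=stimulus_order,
        nonresponders=tuple(bool(v) for v in sub["is_nonresponder"]),
    )


def cpd_features(
    model: CPDModel, drug_index: int, dose_index: int, regime_id: str
) -> FeatureMatrix:
    """15 x R matrix of component weights for one (drug, drug-dose) regime."""
    rows = []
    order = []
    n_doses = model.factors[1].shape[0]
    for i, ligand in enumerate(LIGANDS[: model.factors[0].shape[0]]):
        for j in range(n_doses):
            rows.append(model.weights(i, j, drug_index, dose_index))
            order.append(f"{ligand}_{DOSE_LEVELS[j][0]}")
    return FeatureMatrix(
        space=f"cpd{model.rank}",
        regime_id=regime_id,
        values=np.vstack(rows),
        stimulus_order=tuple(order),
    )


def fpca_features(
    model: FPCAModel,
    tset: TrajectorySet,
    regime_id: str,
) -> FeatureMatrix:
    scores = model.transform(tset.regime_matrix(regime_id))
    return FeatureMatrix(
        space=f"fpca{model.eigenfunctions.shape[0]}",
        regime_id=regime_id,
        values=scores,
        stimulus_order=tset.stimulus_order,
    )


def feature_matrix(
    space: str,
    regime_id: str,
    tset: TrajectorySet | None = None,
    norm_codons: pd.DataFrame | None = None,
    cpd_model: CPDModel | None = None,
    cpd_indices: tuple[int, int] | None = None,
    fpca_model: FPCAModel | None = None,
) -> FeatureMatrix:
    """Dispatch to the requested comparison space.

    Raises MissingModelError when the upstream model or data for the space
    was not supplied.
    """
    if space == "trajectory":
        if tset is None:
            raise MissingModelError("trajectory space needs a TrajectorySet")
        return trajectory_features(tset, regime_id)
    if space == "codon":
        if norm_codons is None or tset is None:
            raise MissingModelError("codon space needs a normalized codon table")
        return codon_features(norm_codons, regime_id, tset.stimulus_order)
    if space.startswith("cpd"):
        if cpd_model is None or cpd_indices is None:
            raise MissingModelError("cpd space needs a fitted CPDModel and indices")
        return cpd_features(cpd_model, *cpd_indices, regime_id=regime_id)
    if space.startswith("fpca"):
        if fpca_model is None or tset is None:
            raise MissingModelError("fpca space needs a fitted FPCAModel")
        return fpca_features(fpca_model, tset, regime_id)
    raise ValueError(f"unknown feature space {space!r}")
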