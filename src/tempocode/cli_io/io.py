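"""Readers and writers for the interchange formats.

Trajectory tables are CSV, UTF-8, '.' decimal, either long
(``regime_id,drug,dd,ligand,ligand_dose,t_min,value``) or wide
(``regime_id,drug,dd,ligand,ligand_dose,t0,t1,...``). Values are rendered
with 17 significant digits so write-then-read round-trips bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from tempocode.codons import CODON_NAMES
from tempocode.sim_engine.grid import TimeGrid, Trajectory
from tempocode.sim_engine.gridsim import TrajectorySet

FLOAT_FMT = "%.17g"
_LABEL_COLS = ["regime_id", "drug", "dd", "ligand", "ligand_dose"]


class TrajectoryParseError(ValueError):
    pass


def _drug_dd(regime_id: str) -> tuple[str, int | None]:
    # single-drug ids follow {drug}_DD{l}; anything else keeps dd = None
    if "_DD" in regime_id and "+" not in regime_id:
        drug, _, dd = regime_id.rpartition("_DD")
        if dd.isdigit():
            return drug, int(dd)
    return regime_id if regime_id != "untreated" else "none", None


def write_trajectories(
    tset: TrajectorySet, path: str | Path, fmt: str = "long"
) -> None:
    path = Path(path)
    rows = []
    times = tset.grid.times
    for rid in tset.regime_ids:
        drug, dd = _drug_dd(rid)
        for label in tset.stimulus_order:
            traj = tset.trajectories[rid][label]
            base = {
                "regime_id": rid,
                "drug": drug,
                "dd": "" if dd is None else dd,
                "ligand": traj.ligand,
                "ligand_dose": traj.ligand_dose,
            }
            if fmt == "long":
                for t, v in zip(times, traj.values):
                    rows.append({**base, "t_min": t, "value": v})
            elif fmt == "wide":
                rows.append(
                    {**base, "dt_min": tset.grid.dt,
                     **{f"t{i}": v for i, v in enumerate(traj.values)}}
                )
            else:
                raise ValueError(f"unknown trajectory format {fmt!r}")
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectories(path: str | Path, fmt: str | None = None) -> TrajectorySet:
    """Read a trajectory table; the dialect is sniffed unless given."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    missing = [c for c in _LABEL_COLS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing label column(s) {missing}")
    if fmt is None:
        fmt = "long" if "t_min" in df.columns else "wide"
    if fmt == "long":
        return _read_long(df, path)
    return _read_wide(df, path)


def _read_long(df: pd.DataFrame, path: Path) -> TrajectorySet:
    for col in ("t_min", "value"):
        if col not in df.columns:
            raise TrajectoryParseError(f"{path}: long format requires {col!r}")
    if df[["t_min", "value"]].isna().any().any():
        bad = int(df[df[["t_min", "value"]].isna().any(axis=1)].index[0]) + 2
        raise TrajectoryParseError(f"{path}: missing value near line {bad}")
    groups = df.groupby(["regime_id", "ligand", "ligand_dose"], sort=False)
    first_t = None
    trajectories: dict[str, dict[str, Trajectory]] = {}
    order: list[str] = []
    regimes: list[str] = []
    grid = None
    for (rid, ligand, dose), g in groups:
        t = g["t_min"].to_numpy(dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise TrajectoryParseError(
                f"{path}: non-monotone or degenerate time column for "
                f"{rid}/{ligand}/{dose}"
            )
        if grid is None:
            dt = t[1] - t[0]
            if not np.allclose(np.diff(t), dt):
                raise TrajectoryParseError(f"{path}: non-uniform time grid")
            grid = TimeGrid(n_points=len(t), dt=float(dt), t_start=float(t[0]))
            first_t = t
        elif len(t) != grid.n_points or not np.array_equal(t, first_t):
            raise TrajectoryParseError(
                f"{path}: inconsistent time grid for {rid}/{ligand}/{dose}"
            )
        label = f"{ligand}_{str(dose)[0]}"
        trajectories.setdefault(rid, {})[label] = Trajectory(
            values=g["value"].to_numpy(dtype=float),
            grid=grid, ligand=str(ligand), ligand_dose=str(dose), regime_id=str(rid),
        )
        if rid not in regimes:
            regimes.append(rid)
        if label not in order:
            order.append(label)
    tset = TrajectorySet(
        grid=grid, stimulus_order=tuple(order), regime_ids=tuple(regimes),
        trajectories=trajectories,
    )
    tset.validate_complete()
    return tset


def _read_wide(df: pd.DataFrame, path: Path) -> TrajectorySet:
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    if len(tcols) < 2:
        raise TrajectoryParseError(f"{path}: wide format requires t0..tN columns")
    expected = [f"t{i}" for i in range(len(tcols))]
    if sorted(tcols, key=lambda c: int(c[1:])) != expected:
        raise TrajectoryParseError(f"{path}: missing timepoint column in t0..tN")
    if df[expected].isna().any().any():
        bad = int(df[df[expected].isna().any(axis=1)].index[0]) + 2
        raise TrajectoryParseError(f"{path}: ragged row near line {bad}")
    grid = TimeGrid(n_points=len(expected), dt=1.0)
    # dt is not stored in the wide dialect; carried via a meta column if present
    if "dt_min" in df.columns:
        grid = TimeGrid(n_points=len(expected), dt=float(df["dt_min"].iloc[0]))
    trajectories: dict[str, dict[str, Trajectory]] = {}
    order: list[str] = []
    regimes: list[str] = []
    for _, row in df.iterrows():
        rid = str(row["regime_id"])
        label = f"{row['ligand']}_{str(row['ligand_dose'])[0]}"
        trajectories.setdefault(rid, {})[label] = Trajectory(
            values=row[expected].to_numpy(dtype=float),
            grid=grid, ligand=str(row["ligand"]),
            ligand_dose=str(row["ligand_dose"]), regime_id=rid,
        )
        if rid not in regimes:
            regimes.append(rid)
        if label not in order:
            order.append(label)
    tset = TrajectorySet(
        grid=grid, stimulus_order=tuple(order), regime_ids=tuple(regimes),
        trajectories=trajectories,
    )
    tset.validate_complete()
    return tset


def write_codon_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_codon_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    required = {"regime_id", "ligand", "ligand_dose", *CODON_NAMES, "is_nonresponder"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_scores(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_matrix(
    matrix: np.ndarray, labels: list[str], path: str | Path
) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(Path(path))


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(Path(path), index_col=0)
    return df.to_numpy(), list(df.index)
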