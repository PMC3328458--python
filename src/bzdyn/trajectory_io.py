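"""Reading and writing the standard formats the pipeline touches.

Trajectories travel as multi-model PDB (MODEL/ENDMDL blocks, ATOM records,
TER between chains) via biotite; tabular data (torsion series, state
series, energy components) travel as headed CSV/TSV with degrees, ps,
Angstrom and kcal/mol on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .duplex_builder import DuplexModel, Residue
from .synthetic_dynamics import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_model",
    "read_energy_table",
    "EnergyTable",
    "ACCEPTED_RESIDUE_NAMES",
    "REQUIRED_ENERGY_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Residue-name aliases accepted on input, mapped to (base letter, methylated).
ACCEPTED_RESIDUE_NAMES = {
    "DG": ("G", False),
    "G": ("G", False),
    "DC": ("C", False),
    "C": ("C", False),
    "5CM": ("C", True),
    "5MC": ("C", True),
}

REQUIRED_ENERGY_COLUMNS = ("E_ELE", "E_VDW", "E_INT", "E_PBCAL")


# ---------------------------------------------------------------------------
# PDB trajectories
# ---------------------------------------------------------------------------


def _model_to_atom_array(model: DuplexModel, coords: np.ndarray) -> bst.AtomArray:
    n = model.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([model.residues[r].chain for r in model.atom_residue])
    arr.res_id = np.array([model.residues[r].number for r in model.atom_residue])
    arr.res_name = np.array([model.residues[r].res_name for r in model.atom_residue])
    arr.atom_name = np.array(model.atom_names)
    arr.element = np.array([nm.strip("'0123456789")[:1] for nm in model.atom_names])
    arr.hetero = np.array([model.residues[r].res_name == "5CM" for r in model.atom_residue])
    return arr


def write_model(model: DuplexModel, path) -> None:
    """Write a single structure as a one-model PDB file."""
    write_trajectory(Trajectory(model.coords[None, :, :], dt=1.0), model, path)


def write_trajectory(traj: Trajectory, model: DuplexModel, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    if traj.n_atoms != model.n_atoms:
        raise ValueError("trajectory and model disagree on atom count")
    stack = bst.stack(
        [_model_to_atom_array(model, traj.frames[i]) for i in range(traj.n_frames)]
    )
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def _scan_models(lines):
    """(model_index, atom_count) pairs from raw PDB lines; a file without
    MODEL records counts as one implicit model if it has ATOM records."""
    counts = []
    current = None
    saw_model = False
    for ln in lines:
        rec = ln[:6].strip()
        if rec == "MODEL":
            saw_model = True
            if current is not None:
                counts.append(current)
            current = 0
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = 0
            current += 1
        elif rec == "ENDMDL":
            if current is not None:
                counts.append(current)
                current = None
    if current is not None and (current > 0 or saw_model):
        counts.append(current)
    return counts


def read_trajectory(path, dt: float = 2.0):
    """Read a multi-model PDB; returns ``(Trajectory, DuplexModel)``.

    The topology (atom names, residues, chains) is taken verbatim from the
    first model; every model must contain the same atoms in the same order.
    """
    path = Path(path)
    text = path.read_text()
    counts = _scan_models(text.splitlines())
    if not counts or sum(counts) == 0:
        raise ValueError(f"no models found in {path}")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"inconsistent atom count across models in {path}: model {bad} has "
            f"{counts[bad - 1]} atoms, model 1 has {counts[0]}"
        )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    first = stack[0]

    residues: list[Residue] = []
    atom_residue = np.empty(first.array_length(), dtype=int)
    key_to_index: dict = {}
    for j in range(first.array_length()):
        res_name = str(first.res_name[j])
        if res_name not in ACCEPTED_RESIDUE_NAMES:
            accepted = ", ".join(sorted(ACCEPTED_RESIDUE_NAMES))
            raise ValueError(
                f"unknown residue name {res_name!r}; accepted names: {accepted}"
            )
        key = (str(first.chain_id[j]), int(first.res_id[j]))
        if key not in key_to_index:
            base, methylated = ACCEPTED_RESIDUE_NAMES[res_name]
            key_to_index[key] = len(residues)
            residues.append(Residue(key[0], key[1], base, methylated))
        atom_residue[j] = key_to_index[key]

    model = DuplexModel(
        residues=residues,
        atom_names=[str(n) for n in first.atom_name],
        atom_residue=atom_residue,
        coords=np.asarray(first.coord, dtype=float),
        form=None,
        step_parameters=None,
    )
    traj = Trajectory(frames=np.asarray(stack.coord, dtype=float), dt=dt)
    return traj, model


# ---------------------------------------------------------------------------
# Tabular data
# ---------------------------------------------------------------------------


@dataclass
class EnergyTable:
    """Per-snapshot MM/PBSA energy components for one system.

    Columns are kcal/mol except ``SA`` (Angstrom^2); ``TS`` holds the
    -T*S entropy contribution when available.
    """

    data: pd.DataFrame
    system: str = ""

    @property
    def n_snapshots(self) -> int:
        return len(self.data)


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_energy_table(path, system: str = "") -> EnergyTable:
    """Read a per-snapshot energy component table (CSV/TSV with header).

    Requires E_ELE, E_VDW, E_INT, E_PBCAL plus either SA (surface area,
    A^2) or a precomputed E_PBSUR; when both are present E_PBSUR takes
    precedence and a warning is logged.  Optional column TS carries -T*S.
    """
    df = _read_delimited(path)
    for col in REQUIRED_ENERGY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    if "E_PBSUR" not in df.columns and "SA" not in df.columns:
        raise ValueError("missing column E_PBSUR (or SA)")
    if "E_PBSUR" in df.columns and "SA" in df.columns:
        logger.warning(
            "both E_PBSUR and SA present in %s; using precomputed E_PBSUR", path
        )
        df = df.drop(columns=["SA"])
    use = [c for c in df.columns if c in
           (*REQUIRED_ENERGY_COLUMNS, "SA", "E_PBSUR", "TS")]
    sub = df[use]
    if sub.isna().any().any():
        bad = int(np.flatnonzero(sub.isna().any(axis=1).to_numpy())[0]) + 2
        raise ValueError(f"missing value in energy table near line {bad}")
    return EnergyTable(data=sub.reset_index(drop=True), system=system)


def write_table(df: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a DataFrame as CSV or TSV (by ``fmt`` or file suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    df.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV written by :func:`write_table`."""
    return _read_delimited(path)
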