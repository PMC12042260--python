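"""Reading and writing structures, trajectories, energy tables and anchors.

The on-disk trajectory dialect is multi-model PDB (``MODEL``/``ENDMDL``
records), parsed and emitted through biotite; a plain single-model PDB is the
degenerate one-frame case.  Energy tables are comma- or tab-delimited text
with columns ``frame, replica, dg_total, dg_lipo, dg_coulomb, dg_hbond`` and
an optional ``# hac = N`` header comment carrying the ligand heavy-atom
count.  Helix-anchor configurations are YAML.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import Frame, SystemLabel, Topology, Trajectory
from .energetics import EnergyTable
from .errors import ConsistencyError, ParseError, StructureError
from .geometry import HelixAnchors
from .core import ResidueSpan
from .roles import assign_roles

ENERGY_COLUMNS = ["frame", "replica", "dg_total", "dg_lipo", "dg_coulomb", "dg_hbond"]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path, dialect: str = "multi_model_pdb", *,
                   replica_id: int = 0,
                   system_label: SystemLabel | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    ``dialect`` is ``"pdb"`` (exactly one model expected) or
    ``"multi_model_pdb"`` (one frame per MODEL record; a model-less file
    counts as one frame).  Role flags are populated from the residue
    template table.
    """
    if dialect not in ("pdb", "multi_model_pdb"):
        raise ParseError(f"unknown dialect '{dialect}'")
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)  # AtomArrayStack
    except Exception as exc:  # biotite raises several parse/shape errors
        msg = str(exc)
        if "model" in msg.lower() or "same" in msg.lower():
            raise StructureError(f"{path}: inconsistent models ({msg})") from exc
        raise ParseError(f"{path}: {msg}") from exc
    if dialect == "pdb" and stack.stack_depth() != 1:
        raise StructureError(
            f"{path}: dialect 'pdb' expects exactly 1 model, found {stack.stack_depth()}"
        )
    first = stack[0]
    n = first.array_length()
    topology = Topology(
        atom_id=np.arange(1, n + 1),
        name=first.atom_name,
        element=first.element,
        residue_number=first.res_id,
        residue_name=first.res_name,
        chain=first.chain_id,
    )
    assign_roles(topology)
    frames = [Frame(index=i, time=float(i), coordinates=stack.coord[i])
              for i in range(stack.stack_depth())]
    return Trajectory(topology=topology, frames=frames, replica_id=replica_id,
                      system_label=system_label or SystemLabel())


def write_structure(trajectory: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (single model if one frame)."""
    top = trajectory.topology
    n = top.n_atoms
    array = struc.AtomArray(n)
    array.chain_id = np.asarray(top.chain, dtype="U4")
    array.res_id = top.residue_number.copy()
    array.res_name = np.asarray(top.residue_name, dtype="U5")
    array.atom_name = np.asarray(top.name, dtype="U6")
    array.element = np.asarray(top.element, dtype="U2")
    array.hetero = top.roles["ligand"] | top.roles["water"]
    coords = trajectory.coordinates()
    stack = struc.from_template(array, coords)
    pdb = PDBFile()
    if trajectory.n_frames == 1:
        pdb.set_structure(stack[0])
    else:
        pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def read_energy_table(path) -> EnergyTable:
    """Read a delimited per-frame binding-energy table.

    Raises :class:`ParseError` naming the first bad row for non-numeric
    cells, and :class:`ConsistencyError` for duplicate (replica, frame) keys.
    """
    hac = 1
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("#"):
        try:
            hac = int(head.split("=")[1])
        except (IndexError, ValueError):
            raise ParseError(f"{path}: malformed header comment '{head.strip()}'")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    df = df[ENERGY_COLUMNS]
    for col in ENERGY_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1  # 1-based data row
            raise ParseError(f"{path}: non-numeric value in column '{col}' at data row {row}")
        df[col] = coerced
    df["frame"] = df["frame"].astype(int)
    df["replica"] = df["replica"].astype(int)
    dup = df.duplicated(subset=["replica", "frame"])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise ConsistencyError(
            f"{path}: duplicate (replica, frame) = ({int(r.replica)}, {int(r.frame)})"
        )
    return EnergyTable(records=df.reset_index(drop=True), hac=hac)


def write_energy_table(table: EnergyTable, path) -> None:
    """Write an energy table in the dialect :func:`read_energy_table` reads."""
    with open(path, "w") as fh:
        fh.write(f"# hac = {table.hac}\n")
        table.records[ENERGY_COLUMNS].to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# anchor configuration
# ---------------------------------------------------------------------------

def _span_from_mapping(entry) -> ResidueSpan:
    return ResidueSpan(chain=str(entry.get("chain", "A")),
                       first_residue=int(entry["first"]),
                       last_residue=int(entry["last"]))


def load_anchors(path) -> dict[str, HelixAnchors]:
    """Load receptor -> helix-anchor spans from a YAML config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for receptor, spans in raw.items():
        try:
            out[receptor] = HelixAnchors(
                receptor=receptor,
                h3b=_span_from_mapping(spans["h3b"]),
                h10=_span_from_mapping(spans["h10"]),
                h12=_span_from_mapping(spans["h12"]),
            )
        except KeyError as exc:
            raise ParseError(f"{path}: receptor '{receptor}' missing span {exc}") from None
    return out


def save_anchors(anchors: dict[str, HelixAnchors], path) -> None:
    raw = {}
    for receptor, a in anchors.items():
        raw[receptor] = {
            key: {"chain": s.chain, "first": s.first_residue, "last": s.last_residue}
            for key, s in (("h3b", a.h3b), ("h10", a.h10), ("h12", a.h12))
        }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
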