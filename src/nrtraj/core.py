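"""Core containers: topology, frames, trajectories, residue spans.

A :class:`Topology` is a flat, array-backed atom table; a :class:`Frame` is one
set of coordinates matched to it; a :class:`Trajectory` bundles an ordered
frame list with replica/system bookkeeping.  Coordinates are Angstrom
throughout and residue spans are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError, StructureError

#: Recognised per-atom role flags.
ROLE_FLAGS = (
    "heavy",
    "c_alpha",
    "backbone",
    "ligand",
    "water",
    "hbond_donor_heavy",
    "hbond_acceptor",
    "hydrophobic_carbon",
    "aromatic_ring_member",
)


@dataclass(frozen=True)
class ResidueSpan:
    """Inclusive 1-based residue range on one chain."""

    chain: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError(
                f"span first_residue {self.first_residue} > last_residue {self.last_residue}"
            )

    def __len__(self) -> int:
        return self.last_residue - self.first_residue + 1

    def residues(self) -> range:
        return range(self.first_residue, self.last_residue + 1)


@dataclass(frozen=True)
class SystemLabel:
    """Identity of a simulated system: receptor, ligand, starting H12 state."""

    receptor: str = "synthetic"
    ligand: str = "LIG"
    start_conformation: str = "AGO"  # AGO | ANT


class Topology:
    """Array-backed atom table with role flags and aromatic-ring bookkeeping.

    Parameters
    ----------
    atom_id, name, element, residue_number, residue_name, chain
        Parallel per-atom arrays/sequences.
    roles
        Mapping role flag -> boolean array; missing flags default to all-False
        except ``heavy``, which is inferred from the element when absent.
    rings
        Aromatic rings as lists of atom_ids (>= 5 atoms each).
    """

    def __init__(self, atom_id, name, element, residue_number, residue_name,
                 chain, roles=None, rings=None):
        self.atom_id = np.asarray(atom_id, dtype=int)
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray([e.upper() for e in element], dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.chain = np.asarray(chain, dtype=object)
        n = self.n_atoms
        roles = dict(roles or {})
        self.roles: dict[str, np.ndarray] = {}
        for flag in ROLE_FLAGS:
            if flag in roles:
                arr = np.asarray(roles[flag], dtype=bool)
                if arr.shape != (n,):
                    raise StructureError(f"role '{flag}' length {arr.shape} != atom count {n}")
                self.roles[flag] = arr
            elif flag == "heavy":
                self.roles[flag] = self.element != "H"
            else:
                self.roles[flag] = np.zeros(n, dtype=bool)
        unknown = set(roles) - set(ROLE_FLAGS)
        if unknown:
            raise StructureError(f"unknown role flags: {sorted(unknown)}")
        self.rings: list[list[int]] = [list(map(int, r)) for r in (rings or [])]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        ids = self.atom_id
        if len(ids) == 0:
            raise StructureError("topology has no atoms")
        if len(np.unique(ids)) != len(ids) or np.any(np.diff(ids) <= 0):
            raise StructureError("atom_ids must be unique and strictly increasing")
        ca = self.roles["c_alpha"]
        if np.any(ca & (self.element != "C")):
            raise StructureError("c_alpha atoms must be carbon")
        if np.any(self.roles["ligand"] & self.roles["c_alpha"]):
            raise StructureError("ligand and protein atom sets must be disjoint")
        for ring in self.rings:
            if len(ring) < 5:
                raise StructureError(f"ring {ring} has fewer than 5 atoms")
            if not set(ring) <= set(ids.tolist()):
                raise StructureError(f"ring {ring} references unknown atom ids")

    # -- basics ----------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def index_of(self, atom_ids) -> np.ndarray:
        """Positions (row indices) of the given atom_ids, order-preserving."""
        lut = {int(a): i for i, a in enumerate(self.atom_id)}
        try:
            return np.asarray([lut[int(a)] for a in np.atleast_1d(atom_ids)], dtype=int)
        except KeyError as exc:
            raise SelectionError(f"unknown atom_id {exc.args[0]}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            np.array_equal(self.atom_id, other.atom_id)
            and np.array_equal(self.name, other.name)
            and np.array_equal(self.element, other.element)
            and np.array_equal(self.residue_number, other.residue_number)
            and np.array_equal(self.residue_name, other.residue_name)
            and np.array_equal(self.chain, other.chain)
        )


_QUERY_FIELDS = {"chain", "residue_number", "residue_range", "residue_name",
                 "name", "element", "role", "span"}


def select_atoms(topology: Topology, **query) -> list[int]:
    """Select atom_ids matching every given criterion (AND semantics).

    Supported keywords: ``chain``, ``residue_number``, ``residue_range``
    (inclusive 2-tuple), ``residue_name``, ``name``, ``element``, ``role``
    (a flag name or list of flags, all required), ``span`` (a
    :class:`ResidueSpan`, shorthand for chain + residue_range).  The result is
    ordered by atom_id and may be empty; the same query always returns the
    same list.
    """
    unknown = set(query) - _QUERY_FIELDS
    if unknown:
        raise SelectionError(f"unknown query field(s): {sorted(unknown)}")
    mask = np.ones(topology.n_atoms, dtype=bool)
    span = query.pop("span", None)
    if span is not None:
        query.setdefault("chain", span.chain)
        query.setdefault("residue_range", (span.first_residue, span.last_residue))
    for key, value in query.items():
        if key == "chain":
            mask &= topology.chain == value
        elif key == "residue_number":
            mask &= topology.residue_number == int(value)
        elif key == "residue_range":
            lo, hi = value
            mask &= (topology.residue_number >= int(lo)) & (topology.residue_number <= int(hi))
        elif key == "residue_name":
            mask &= topology.residue_name == value
        elif key == "name":
            mask &= topology.name == value
        elif key == "element":
            mask &= topology.element == value.upper()
        elif key == "role":
            flags = [value] if isinstance(value, str) else list(value)
            for flag in flags:
                if flag not in ROLE_FLAGS:
                    raise SelectionError(f"unknown role flag '{flag}'")
                mask &= topology.roles[flag]
    return [int(a) for a in topology.atom_id[mask]]


@dataclass
class Frame:
    """One coordinate set; ``coordinates`` is an (n_atoms, 3) float array in A."""

    index: int
    time: float  # picoseconds
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError(f"frame {self.index}: non-finite coordinates")


@dataclass
class Trajectory:
    """Topology plus ordered frames with replica/system labels."""

    topology: Topology
    frames: list[Frame]
    replica_id: int = 0
    system_label: SystemLabel = field(default_factory=SystemLabel)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise StructureError("trajectory needs at least one frame")
        n = self.topology.n_atoms
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("frame indices must be strictly increasing")
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {f.index}: {f.coordinates.shape[0]} coordinates for {n} atoms"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])
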