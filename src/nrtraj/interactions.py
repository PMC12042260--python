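"""Geometric protein-ligand interaction detectors and occupancy aggregation.

Detection criteria follow the simulation-interaction-analysis defaults common
in the field: an H-bond requires hydrogen-acceptor distance <= 2.5 A, a
donor angle (D-H...A) >= 120 deg and an acceptor angle (H...A-X) >= 90 deg;
hydrophobic contacts use a 3.6 A carbon-carbon cutoff; water bridges use the
same H-bond test at 2.8 A / 110 deg / 90 deg on both legs; pi-pi stacking is
face-to-face (centroid distance <= 4.4 A, interplanar angle <= 30 deg) or
edge-to-face (<= 5.5 A, >= 60 deg).  All thresholds live in
:class:`InteractionCriteria`.

Occupancy is the fraction of trajectory frames in which a residue forms at
least one interaction of a given kind with the ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory
from .errors import ConsistencyError, TopologyError

#: Max covalent H - heavy-atom distance used to find attached hydrogens (A).
H_COVALENT_CUTOFF = 1.25
#: Max covalent heavy - heavy distance used to find the acceptor antecedent (A).
HEAVY_COVALENT_CUTOFF = 1.9


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for every detector (distances A, angles deg)."""

    hbond_distance: float = 2.5
    hbond_donor_angle: float = 120.0
    hbond_acceptor_angle: float = 90.0
    hydrophobic_distance: float = 3.6
    waterbridge_distance: float = 2.8
    waterbridge_donor_angle: float = 110.0
    waterbridge_acceptor_angle: float = 90.0
    pipi_facetoface_distance: float = 4.4
    pipi_edgetoface_distance: float = 5.5
    pipi_face_angle: float = 30.0
    pipi_edge_angle: float = 60.0

    def __post_init__(self) -> None:
        for f in ("hbond_distance", "hydrophobic_distance", "waterbridge_distance",
                  "pipi_facetoface_distance", "pipi_edgetoface_distance"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("hbond_donor_angle", "hbond_acceptor_angle",
                  "waterbridge_donor_angle", "waterbridge_acceptor_angle",
                  "pipi_face_angle", "pipi_edge_angle"):
            if not 0 < getattr(self, f) < 180:
                raise ValueError(f"{f} must be in (0, 180)")

    def loosened(self, **deltas) -> "InteractionCriteria":
        """Copy with named distance fields increased by the given amounts."""
        return replace(self, **{k: getattr(self, k) + v for k, v in deltas.items()})


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    kind: str  # hbond | hydrophobic | pipi | water_bridge
    protein_residue: tuple  # (chain, number, name)
    ligand_atom: int
    bridging_water: Optional[tuple] = None  # (chain, number) of the water

    def __post_init__(self) -> None:
        if self.kind == "water_bridge" and self.bridging_water is None:
            raise ConsistencyError("water_bridge event requires bridging_water")


# ---------------------------------------------------------------------------
# topology helpers
# ---------------------------------------------------------------------------

def _residue_key(top: Topology, idx: int) -> tuple:
    return (str(top.chain[idx]), int(top.residue_number[idx]), str(top.residue_name[idx]))


def _attached_hydrogens(frame: Frame, top: Topology, heavy_idx: int) -> list[int]:
    """Row indices of hydrogens covalently attached to a heavy atom."""
    same_res = ((top.chain == top.chain[heavy_idx])
                & (top.residue_number == top.residue_number[heavy_idx])
                & (top.element == "H"))
    cand = np.where(same_res)[0]
    if len(cand) == 0:
        return []
    d = np.linalg.norm(frame.coordinates[cand] - frame.coordinates[heavy_idx], axis=1)
    return [int(c) for c, dd in zip(cand, d) if dd <= H_COVALENT_CUTOFF]


def _acceptor_antecedent(frame: Frame, top: Topology, acc_idx: int) -> Optional[int]:
    """Bonded partner X of an acceptor for the H...A-X angle (heavy preferred)."""
    same_res = ((top.chain == top.chain[acc_idx])
                & (top.residue_number == top.residue_number[acc_idx]))
    cand = np.where(same_res)[0]
    cand = cand[cand != acc_idx]
    if len(cand) == 0:
        return None
    d = np.linalg.norm(frame.coordinates[cand] - frame.coordinates[acc_idx], axis=1)
    heavy = [(c, dd) for c, dd in zip(cand, d)
             if top.element[c] != "H" and dd <= HEAVY_COVALENT_CUTOFF]
    if heavy:
        return int(min(heavy, key=lambda t: t[1])[0])
    hyd = [(c, dd) for c, dd in zip(cand, d)
           if top.element[c] == "H" and dd <= H_COVALENT_CUTOFF]
    if hyd:
        return int(min(hyd, key=lambda t: t[1])[0])
    return None


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _hbond_geometry_ok(frame: Frame, top: Topology, donor: int, hyd: int, acc: int,
                       dist: float, donor_angle: float, acceptor_angle: float) -> bool:
    xyz = frame.coordinates
    if np.linalg.norm(xyz[hyd] - xyz[acc]) > dist:
        return False
    if _angle(xyz[donor], xyz[hyd], xyz[acc]) < donor_angle:
        return False
    x = _acceptor_antecedent(frame, top, acc)
    if x is not None and _angle(xyz[hyd], xyz[acc], xyz[x]) < acceptor_angle:
        return False
    return True


def _hbond_pairs(frame: Frame, top: Topology, donor_rows, acceptor_rows,
                 dist: float, donor_angle: float, acceptor_angle: float,
                 strict: bool):
    """All (donor, hydrogen, acceptor) row triples satisfying the H-bond test.

    ``strict`` raises for protein donors lacking an attached hydrogen;
    element-typed (ligand/water) potential donors without hydrogens are
    skipped silently since element typing over-approximates donor capacity.
    """
    out = []
    for don in donor_rows:
        hyds = _attached_hydrogens(frame, top, don)
        if not hyds:
            if strict and not (top.roles["ligand"][don] or top.roles["water"][don]):
                raise TopologyError(
                    f"donor atom id {int(top.atom_id[don])} "
                    f"({_residue_key(top, don)}/{top.name[don]}) has no attached hydrogen"
                )
            continue
        for acc in acceptor_rows:
            if acc == don:
                continue
            for hyd in hyds:
                if _hbond_geometry_ok(frame, top, don, hyd, acc,
                                      dist, donor_angle, acceptor_angle):
                    out.append((don, hyd, acc))
                    break  # one qualifying hydrogen is enough for this pair
    return out


def _rows(top: Topology, *flags, invert_ligand=None) -> np.ndarray:
    mask = np.ones(top.n_atoms, dtype=bool)
    for f in flags:
        mask &= top.roles[f]
    if invert_ligand is True:
        mask &= top.roles["ligand"]
    elif invert_ligand is False:
        mask &= ~top.roles["ligand"] & ~top.roles["water"]
    return np.where(mask)[0]


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_hbonds(frame: Frame, topology: Topology,
                  criteria: InteractionCriteria = InteractionCriteria()) -> list[InteractionEvent]:
    """Protein-ligand hydrogen bonds in one frame (both donation directions)."""
    prot_don = _rows(topology, "hbond_donor_heavy", invert_ligand=False)
    prot_acc = _rows(topology, "hbond_acceptor", invert_ligand=False)
    lig_don = _rows(topology, "hbond_donor_heavy", invert_ligand=True)
    lig_acc = _rows(topology, "hbond_acceptor", invert_ligand=True)
    args = (criteria.hbond_distance, criteria.hbond_donor_angle,
            criteria.hbond_acceptor_angle)
    events = []
    for don, _h, acc in _hbond_pairs(frame, topology, prot_don, lig_acc, *args, strict=True):
        events.append(InteractionEvent(frame=frame.index, kind="hbond",
                                       protein_residue=_residue_key(topology, don),
                                       ligand_atom=int(topology.atom_id[acc])))
    for don, _h, acc in _hbond_pairs(frame, topology, lig_don, prot_acc, *args, strict=False):
        events.append(InteractionEvent(frame=frame.index, kind="hbond",
                                       protein_residue=_residue_key(topology, acc),
                                       ligand_atom=int(topology.atom_id[don])))
    return events


def detect_hydrophobic(frame: Frame, topology: Topology,
                       criteria: InteractionCriteria = InteractionCriteria()) -> list[InteractionEvent]:
    """Hydrophobic carbon-carbon contacts, collapsed to one event per residue."""
    prot = _rows(topology, "hydrophobic_carbon", invert_ligand=False)
    lig = _rows(topology, "hydrophobic_carbon", invert_ligand=True)
    if len(prot) == 0 or len(lig) == 0:
        return []
    d = np.linalg.norm(frame.coordinates[prot][:, None, :]
                       - frame.coordinates[lig][None, :, :], axis=2)
    events = []
    seen = set()
    for pi, li in zip(*np.where(d <= criteria.hydrophobic_distance)):
        key = _residue_key(topology, prot[pi])
        if key in seen:
            continue
        seen.add(key)
        events.append(InteractionEvent(frame=frame.index, kind="hydrophobic",
                                       protein_residue=key,
                                       ligand_atom=int(topology.atom_id[lig[li]])))
    return events


def _ring_centroid_normal(frame: Frame, top: Topology, ring: list[int]):
    if len(ring) < 5:
        raise TopologyError(f"ring {ring} has fewer than 5 atoms")
    xyz = frame.coordinates[top.index_of(ring)]
    centroid = xyz.mean(axis=0)
    _, _, vh = np.linalg.svd(xyz - centroid)
    return centroid, vh[2]  # least-variance direction = plane normal


def detect_pipi(frame: Frame, topology: Topology,
                criteria: InteractionCriteria = InteractionCriteria()) -> list[InteractionEvent]:
    """Face-to-face / edge-to-face aromatic stacking between protein and ligand rings."""
    lig_flag = topology.roles["ligand"]
    prot_rings, lig_rings = [], []
    for ring in topology.rings:
        idx = topology.index_of(ring)
        (lig_rings if lig_flag[idx].all() else prot_rings).append(ring)
    events = []
    for pring in prot_rings:
        pc, pn = _ring_centroid_normal(frame, topology, pring)
        pkey = _residue_key(topology, topology.index_of(pring[0])[0])
        for lring in lig_rings:
            lc, ln = _ring_centroid_normal(frame, topology, lring)
            dist = float(np.linalg.norm(pc - lc))
            ang = _angle(pn, np.zeros(3), ln)
            ang = min(ang, 180.0 - ang)  # interplanar angle in [0, 90]
            face = dist <= criteria.pipi_facetoface_distance and ang <= criteria.pipi_face_angle
            edge = dist <= criteria.pipi_edgetoface_distance and ang >= criteria.pipi_edge_angle
            if face or edge:
                events.append(InteractionEvent(frame=frame.index, kind="pipi",
                                               protein_residue=pkey,
                                               ligand_atom=int(lring[0])))
    return events


def detect_water_bridges(frame: Frame, topology: Topology,
                         criteria: InteractionCriteria = InteractionCriteria()) -> list[InteractionEvent]:
    """Water molecules simultaneously H-bonded to a protein residue and the ligand.

    Both legs use the water-bridge criteria; each leg may have the water as
    donor or acceptor.  One event is emitted per (water, protein residue,
    ligand atom) combination.
    """
    args = (criteria.waterbridge_distance, criteria.waterbridge_donor_angle,
            criteria.waterbridge_acceptor_angle)
    top = topology
    prot_don = _rows(top, "hbond_donor_heavy", invert_ligand=False)
    prot_acc = _rows(top, "hbond_acceptor", invert_ligand=False)
    lig_don = _rows(top, "hbond_donor_heavy", invert_ligand=True)
    lig_acc = _rows(top, "hbond_acceptor", invert_ligand=True)
    water_rows = np.where(top.roles["water"] & top.roles["heavy"])[0]
    events = []
    for w in water_rows:
        wkey = (str(top.chain[w]), int(top.residue_number[w]))
        # protein leg: water donates to protein acceptor or accepts from protein donor
        prot_partners = set()
        for _d, _h, acc in _hbond_pairs(frame, top, [w], prot_acc, *args, strict=False):
            prot_partners.add(_residue_key(top, acc))
        for don, _h, _a in _hbond_pairs(frame, top, prot_don, [w], *args, strict=True):
            prot_partners.add(_residue_key(top, don))
        if not prot_partners:
            continue
        lig_partners = set()
        for _d, _h, acc in _hbond_pairs(frame, top, [w], lig_acc, *args, strict=False):
            lig_partners.add(int(top.atom_id[acc]))
        for don, _h, _a in _hbond_pairs(frame, top, lig_don, [w], *args, strict=False):
            lig_partners.add(int(top.atom_id[don]))
        for pres in sorted(prot_partners):
            for lat in sorted(lig_partners):
                events.append(InteractionEvent(frame=frame.index, kind="water_bridge",
                                               protein_residue=pres, ligand_atom=lat,
                                               bridging_water=wkey))
    return events


def detect_all(frame: Frame, topology: Topology,
               criteria: InteractionCriteria = InteractionCriteria()) -> list[InteractionEvent]:
    """All four detectors on one frame; overlapping categories both reported."""
    return (detect_hbonds(frame, topology, criteria)
            + detect_hydrophobic(frame, topology, criteria)
            + detect_pipi(frame, topology, criteria)
            + detect_water_bridges(frame, topology, criteria))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def occupancy(traj: Trajectory, events: list[InteractionEvent]) -> pd.DataFrame:
    """Per-(residue, kind) fraction of frames with at least one event.

    Returns a DataFrame with columns chain, residue_number, residue_name,
    kind, fraction.  A frame counts once per (residue, kind) no matter how
    many events it contains.  Denominator is the full frame count of the
    trajectory.
    """
    frame_ids = {f.index for f in traj.frames}
    hit_frames: dict[tuple, set] = {}
    for ev in events:
        if ev.frame not in frame_ids:
            raise ConsistencyError(f"event frame {ev.frame} not in trajectory")
        hit_frames.setdefault((ev.protein_residue, ev.kind), set()).add(ev.frame)
    rows = [
        {"chain": res[0], "residue_number": res[1], "residue_name": res[2],
         "kind": kind, "fraction": len(frames) / traj.n_frames}
        for (res, kind), frames in sorted(hit_frames.items(),
                                          key=lambda kv: (kv[0][0][0], kv[0][0][1], kv[0][1]))
    ]
    return pd.DataFrame(rows, columns=["chain", "residue_number", "residue_name",
                                       "kind", "fraction"])


def occupancy_series(traj: Trajectory,
                     criteria: InteractionCriteria = InteractionCriteria()) -> pd.DataFrame:
    """Run all detectors over a trajectory and aggregate occupancies."""
    events = []
    for frame in traj.frames:
        events.extend(detect_all(frame, traj.topology, criteria))
    return occupancy(traj, events)
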