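"""Synthetic fixtures for every pipeline stage.

Four generators, all pure functions of their arguments including the seed:

* :func:`build_ideal_helix` — a parametric alpha-helix (backbone N/CA/C on
  calibrated cylinders) used as a geometric oracle.
* :func:`simulate_bundle` — a three-helix bundle whose mobile helix (H12) is
  rigidly repositioned every frame so that the measured inter-helix angles
  (Ang1, Ang2) and the H12-H10 centroid distance are i.i.d. draws from
  regime-controlled normals, with H12 helicity dialed by partially unfolding
  its backbone.  The agonist-like regime is narrow and docked, the
  antagonist-like regime broad and displaced.
* :func:`plant_complex` — a toy pocket/ligand pair in which each requested
  interaction is realised with qualifying geometry in an exact fraction of
  frames and parked outside the criteria (by a safety margin) elsewhere.
* :func:`synth_energy_table` — replica-structured Gaussian energy streams
  with optional planted outlier replicas.

None of this emulates force-field dynamics; frames are i.i.d. by design so
that descriptor estimators can be checked against known generator inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, ResidueSpan, SystemLabel, Topology, Trajectory
from .energetics import EnergyTable
from .errors import GeneratorError
from .geometry import HelixAnchors
from .roles import assign_roles

# Cylindrical offsets for backbone N and C relative to the C-alpha wheel,
# calibrated so that the default helix (rise 1.5 A, twist 100 deg, C-alpha
# radius 2.3 A) has phi = -57 deg, psi = -47 deg and standard bond lengths.
_N_RADIUS, _N_PHASE, _N_ZOFF = 1.631721, -0.462521, -0.943675
_C_RADIUS, _C_PHASE, _C_ZOFF = 1.675126, 0.503659, 0.989090

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)

# NeRF internal coordinates (A / deg): N-CA 1.458, CA-C 1.525, C-N 1.329;
# angles N-CA-C 111.2, CA-C-N 116.2, C-N-CA 121.7; omega fixed at 180.
_BOND_N_CA, _BOND_CA_C, _BOND_C_N = 1.458, 1.525, 1.329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return -np.eye(3) + 2.0 * np.outer(perp, perp)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _rotate_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (unit) axis by an angle in degrees."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _backbone_topology(residue_numbers, chain="A", resname="ALA",
                       first_atom_id=1) -> Topology:
    names, elements, resnums = [], [], []
    for r in residue_numbers:
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            names.append(nm)
            elements.append(el)
            resnums.append(r)
    n = len(names)
    top = Topology(
        atom_id=np.arange(first_atom_id, first_atom_id + n),
        name=names, element=elements, residue_number=resnums,
        residue_name=[resname] * n, chain=[chain] * n,
    )
    assign_roles(top)
    return top


def build_ideal_helix(n_residues: int, rise: float = 1.5, twist: float = 100.0,
                      radius: float = 2.3, axis=(0.0, 0.0, 1.0),
                      chain: str = "A", first_residue: int = 1) -> tuple[Topology, Frame]:
    """Parametric alpha-helix backbone (N/CA/C) along ``axis``.

    C-alpha atoms sit exactly on the requested cylinder (so consecutive
    C-alpha axial spacing equals ``rise`` by construction); N and C ride on
    calibrated companion cylinders that give ideal alpha dihedrals at the
    default geometry.
    """
    if n_residues < 8:
        raise GeneratorError(f"ideal helix needs >= 8 residues, got {n_residues}")
    tw = np.radians(twist)
    coords = []
    for i in range(n_residues):
        th, z = i * tw, i * rise
        coords.append([_N_RADIUS * np.cos(th + _N_PHASE),
                       _N_RADIUS * np.sin(th + _N_PHASE), z + _N_ZOFF])
        coords.append([radius * np.cos(th), radius * np.sin(th), z])
        coords.append([_C_RADIUS * np.cos(th + _C_PHASE),
                       _C_RADIUS * np.sin(th + _C_PHASE), z + _C_ZOFF])
    coords = np.asarray(coords)
    R = _rotation_between(np.array([0.0, 0.0, 1.0]), np.asarray(axis, dtype=float))
    coords = coords @ R.T
    top = _backbone_topology(range(first_residue, first_residue + n_residues), chain=chain)
    return top, Frame(index=0, time=0.0, coordinates=coords)


def _nerf_place(a, b, c, bond, angle_deg, dihedral_deg) -> np.ndarray:
    """Place atom D given A-B-C with |C-D|, angle(B,C,D) and dihedral(A,B,C,D)."""
    theta = np.radians(angle_deg)
    tau = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(tau),
                        bond * np.sin(theta) * np.sin(tau)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]], chain: str = "A",
                   first_residue: int = 1) -> tuple[Topology, Frame]:
    """Backbone chain from per-residue (phi, psi) dihedrals via chain extension.

    ``phi_psi[i]`` gives the dihedrals flanking residue i's C-alpha; phi of
    the first residue and psi of the last are unused.  Omega is 180.
    """
    n = len(phi_psi)
    if n < 2:
        raise GeneratorError("backbone needs >= 2 residues")
    coords = np.zeros((3 * n, 3))
    # first residue laid flat in the xy-plane
    coords[0] = [0.0, 0.0, 0.0]                                   # N
    coords[1] = [_BOND_N_CA, 0.0, 0.0]                            # CA
    th = np.radians(180.0 - _ANG_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])  # C
    for i in range(1, n):
        Nprev, CAprev, Cprev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        psi_prev = phi_psi[i - 1][1]
        Ni = _nerf_place(Nprev, CAprev, Cprev, _BOND_C_N, _ANG_CA_C_N, psi_prev)
        CAi = _nerf_place(CAprev, Cprev, Ni, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        Ci = _nerf_place(Cprev, Ni, CAi, _BOND_CA_C, _ANG_N_CA_C, phi_psi[i][0])
        coords[3 * i:3 * i + 3] = [Ni, CAi, Ci]
    top = _backbone_topology(range(first_residue, first_residue + n), chain=chain)
    return top, Frame(index=0, time=0.0, coordinates=coords)


# ---------------------------------------------------------------------------
# regime-controlled bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimeParams:
    """Generator settings for one H12-dynamics regime.

    The shipped defaults put the agonist-like regime at a narrow docked
    geometry (Ang1 70 +/- 3 deg, Ang2 55 +/- 4 deg, high helicity) and the
    antagonist-like regime at a broad displaced one (Ang1 100 +/- 12 deg,
    Ang2 135 +/- 20 deg, reduced helicity).
    """

    regime: str
    ang1_mean: float
    ang1_sd: float
    ang2_mean: float
    ang2_sd: float
    h12_h10_distance_mean: float
    h12_h10_distance_sd: float
    helix_content_mean: float
    n_frames: int = 500
    seed: int = 0
    anchor_jitter_sd: float = 0.15  # per-frame Gaussian noise on H3b/H10 (A)

    def __post_init__(self) -> None:
        for f in ("ang1_sd", "ang2_sd", "h12_h10_distance_sd", "anchor_jitter_sd"):
            if getattr(self, f) < 0:
                raise GeneratorError(f"{f} must be >= 0")
        if not 0.0 <= self.helix_content_mean <= 1.0:
            raise GeneratorError("helix_content_mean must be in [0, 1]")


def agonist_params(n_frames: int = 500, seed: int = 0, **overrides) -> RegimeParams:
    kw = dict(regime="agonist_like", ang1_mean=70.0, ang1_sd=3.0,
              ang2_mean=55.0, ang2_sd=4.0, h12_h10_distance_mean=12.0,
              h12_h10_distance_sd=0.5, helix_content_mean=0.95,
              n_frames=n_frames, seed=seed)
    kw.update(overrides)
    return RegimeParams(**kw)


def antagonist_params(n_frames: int = 500, seed: int = 0, **overrides) -> RegimeParams:
    kw = dict(regime="antagonist_like", ang1_mean=100.0, ang1_sd=12.0,
              ang2_mean=135.0, ang2_sd=20.0, h12_h10_distance_mean=22.0,
              h12_h10_distance_sd=2.0, helix_content_mean=0.6,
              n_frames=n_frames, seed=seed)
    kw.update(overrides)
    return RegimeParams(**kw)


def synthetic_anchors() -> HelixAnchors:
    """Anchor spans matching the topology laid down by :func:`simulate_bundle`."""
    return HelixAnchors(receptor="synthetic",
                        h3b=ResidueSpan("A", 1, 24),
                        h10=ResidueSpan("A", 31, 44),
                        h12=ResidueSpan("A", 51, 62))


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise GeneratorError(f"could not draw from N({mean}, {sd}) within ({lo}, {hi})")


def _centroid_first_last4(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return ca[:4].mean(axis=0), ca[-4:].mean(axis=0)


def simulate_bundle(params: RegimeParams,
                    anchors: HelixAnchors | None = None,
                    replica_id: int = 0,
                    system_label: SystemLabel | None = None) -> Trajectory:
    """Three-helix bundle trajectory with exactly-realised H12 descriptors.

    H3b and H10 are ideal helices (plus small per-frame jitter); H12 is
    rebuilt each frame with a regime-controlled fraction of helical
    residues, then rigidly placed so that the *measured* Ang2 (H12/H10 axis
    angle), Ang1 (vertex angle at the H10 end between the H3b midpoint and
    the H12 end) and H12-H10 centroid distance equal i.i.d. truncated-normal
    draws from the regime parameters.  Draws whose geometry is infeasible
    (no valid placement) are redrawn; more than 10% redraws aborts.
    """
    anchors = anchors or synthetic_anchors()
    n3, n10, n12 = len(anchors.h3b), len(anchors.h10), len(anchors.h12)
    rng = np.random.default_rng(params.seed)

    # static scaffold: H10 along +z at the origin, H3b parallel at x = +12 A
    top10, f10 = build_ideal_helix(n10, first_residue=anchors.h10.first_residue)
    top3, f3 = build_ideal_helix(n3, first_residue=anchors.h3b.first_residue)
    xyz10 = f10.coordinates
    xyz3 = f3.coordinates + np.array([12.0, 0.0, -0.25 * n3 * 1.5])

    n_atoms_12 = 3 * n12
    all_resnums = (list(anchors.h3b.residues()) + list(anchors.h10.residues())
                   + list(anchors.h12.residues()))
    topology = _backbone_topology(all_resnums, chain=anchors.h12.chain)

    ca_rows_3 = np.arange(n3) * 3 + 1
    ca_rows_10 = np.arange(n10) * 3 + 1

    frames = []
    redraws = 0
    budget = max(10, int(0.1 * params.n_frames))
    for k in range(params.n_frames):
        j3 = xyz3 + rng.normal(0.0, params.anchor_jitter_sd, xyz3.shape)
        j10 = xyz10 + rng.normal(0.0, params.anchor_jitter_sd, xyz10.shape)
        s3, e3 = _centroid_first_last4(j3[ca_rows_3])
        s10, e10 = _centroid_first_last4(j10[ca_rows_10])
        M = 0.5 * (s3 + e3)          # H3b axis midpoint
        V = e10                      # H10/H12 inflection vertex
        a10 = e10 - s10              # measured H10 axis vector
        a10u = a10 / np.linalg.norm(a10)
        G = j10.mean(axis=0)         # H10 span centroid
        u = M - V
        u /= np.linalg.norm(u)

        # per-frame H12 template with dialed helicity
        n_hel = int(np.clip(round(params.helix_content_mean * n12
                                  + rng.normal(0.0, 0.5)), 2, n12))
        phi_psi = [HELIX_PHI_PSI] * n_hel + [EXTENDED_PHI_PSI] * (n12 - n_hel)
        _, f12 = build_backbone(phi_psi, first_residue=anchors.h12.first_residue)
        t12 = f12.coordinates
        ca12 = t12[np.arange(n12) * 3 + 1]
        s0, e0 = _centroid_first_last4(ca12)
        c0 = t12.mean(axis=0)

        placed = None
        while placed is None:
            ang1 = _truncated_normal(rng, params.ang1_mean, params.ang1_sd, 0.0, 180.0)
            ang2 = _truncated_normal(rng, params.ang2_mean, params.ang2_sd, 0.0, 180.0)
            dist = _truncated_normal(rng, params.h12_h10_distance_mean,
                                     params.h12_h10_distance_sd, 0.0, np.inf)
            # orientation: H12 axis at ang2 from the measured H10 axis
            perp = np.cross(a10u, u)
            perp /= np.linalg.norm(perp)
            d12 = _rotate_about(perp, ang2) @ a10u
            Q = _rotation_between(e0 - s0, d12)
            # axis-end direction: at ang1 from u, rotating within the (u, a10) plane
            w = _rotate_about(perp, -ang1) @ u
            c_off = Q @ (c0 - e0)     # vector from placed axis end to placed centroid
            b = V + c_off - G
            bw = float(np.dot(b, w))
            disc = bw * bw - (float(np.dot(b, b)) - dist * dist)
            if disc < 0:
                redraws += 1
                if redraws > budget:
                    raise GeneratorError(
                        f"regime '{params.regime}': > {budget} infeasible draws; "
                        "check distance/angle parameter compatibility")
                continue
            R = -bw + np.sqrt(disc)
            if R <= 0:
                redraws += 1
                if redraws > budget:
                    raise GeneratorError(
                        f"regime '{params.regime}': > {budget} infeasible draws")
                continue
            E = V + R * w
            placed = t12 @ Q.T + (E - Q @ e0)

        coords = np.vstack([j3, j10, placed])
        frames.append(Frame(index=k, time=float(k), coordinates=coords))

    return Trajectory(topology=topology, frames=frames, replica_id=replica_id,
                      system_label=system_label
                      or SystemLabel(receptor="synthetic", ligand=params.regime,
                                     start_conformation="AGO"))


# ---------------------------------------------------------------------------
# planted-interaction complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionPlantSpec:
    """One interaction to realise in an exact fraction of frames.

    ``geometry`` optionally overrides the canonical qualifying geometry of
    the kind (keys depend on kind, e.g. distance / donor_angle /
    acceptor_angle for hbond); values must stay strictly inside the criteria
    by >= 0.05 A / 2 deg.
    """

    kind: str  # hbond | hydrophobic | pipi | water_bridge
    presence_fraction: float
    geometry: dict = field(default_factory=dict)
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_fraction <= 1.0:
            raise GeneratorError("presence_fraction must be in [0, 1]")
        if self.kind not in ("hbond", "hydrophobic", "pipi", "water_bridge"):
            raise GeneratorError(f"unknown interaction kind '{self.kind}'")


#: Protein residue targeted by each plant kind in the toy pocket.
PLANT_TARGETS = {"hbond": ("A", 10, "GLU"), "hydrophobic": ("A", 11, "LEU"),
                 "pipi": ("A", 12, "PHE"), "water_bridge": ("A", 10, "GLU")}

_FAR = np.array([0.0, 0.0, 30.0])  # parking offset for "absent" frames


def _hexagon(center, normal, radius=1.39) -> np.ndarray:
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = np.radians(np.arange(6) * 60.0)
    return center + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))


def plant_complex(specs: list[InteractionPlantSpec], n_frames: int,
                  seed: int = 0, replica_id: int = 0,
                  system_label: SystemLabel | None = None) -> Trajectory:
    """Toy pocket + ligand with each interaction planted at an exact occupancy.

    Each spec is realised in exactly ``round(presence_fraction * n_frames)``
    frames (chosen by a seeded permutation) with geometry strictly inside
    the detection criteria, and parked far outside them in the remaining
    frames.  Different kinds use disjoint moving atoms, so their occupancies
    are independent.
    """
    if n_frames < 1:
        raise GeneratorError("n_frames must be >= 1")
    kinds = [s.kind for s in specs]
    if len(set(kinds)) != len(kinds):
        raise GeneratorError("at most one plant spec per interaction kind")
    rng = np.random.default_rng(seed)

    # --- static pocket scaffold (fractional coordinates chosen for isolation)
    atoms = []  # (name, element, resnum, resname, base_xyz)

    def add(name, element, resnum, resname, xyz):
        atoms.append((name, element, resnum, resname, np.asarray(xyz, dtype=float)))

    # GLU 10: carboxylate acceptor (OE1 for the direct H-bond, OE2 for the bridge)
    add("CA", "C", 10, "GLU", (-3.0, -2.0, 0.0))
    add("CB", "C", 10, "GLU", (-3.4, -0.9, 0.0))
    add("CG", "C", 10, "GLU", (-2.5, 0.2, 0.0))
    add("CD", "C", 10, "GLU", (-1.25, 0.0, 0.0))
    add("OE1", "O", 10, "GLU", (0.0, 0.0, 0.0))
    add("OE2", "O", 10, "GLU", (-1.9, 1.1, 0.0))
    # LEU 11: hydrophobic side chain
    add("CA", "C", 11, "LEU", (22.0, 0.0, 0.0))
    add("CB", "C", 11, "LEU", (21.0, 0.8, 0.0))
    add("CG", "C", 11, "LEU", (20.3, 0.0, 0.0))
    add("CD1", "C", 11, "LEU", (20.0, 0.0, 1.5))
    add("CD2", "C", 11, "LEU", (19.2, 0.6, -0.8))
    # PHE 12: aromatic ring in the z = 0 plane at (0, 22)
    add("CA", "C", 12, "PHE", (-2.5, 22.0, 0.0))
    add("CB", "C", 12, "PHE", (-1.8, 22.6, 0.0))
    for nm, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                       _hexagon(np.array([0.0, 22.0, 0.0]), (0, 0, 1))):
        add(nm, "C", 12, "PHE", xyz)
    # SER 13: a protein donor with its hydrogen (strict-donor bookkeeping)
    add("CA", "C", 13, "SER", (22.0, 22.0, 0.0))
    add("CB", "C", 13, "SER", (21.2, 22.6, 0.0))
    add("OG", "O", 13, "SER", (20.2, 21.9, 0.0))
    add("HG", "H", 13, "SER", (19.4, 22.4, 0.0))
    # water 50 (mobile for the bridge plant)
    add("O", "O", 50, "HOH", (-40.0, -40.0, 0.0))
    add("H1", "H", 50, "HOH", (-39.2, -40.5, 0.0))
    add("H2", "H", 50, "HOH", (-40.6, -40.7, 0.0))
    # ligand: ring C1-C6 (pipi mover), C7 (hydrophobic mover),
    # O1/H1 (hbond donor mover), O2 (bridge acceptor, static)
    for nm, xyz in zip(("C1", "C2", "C3", "C4", "C5", "C6"),
                       _hexagon(np.array([0.0, 22.0, 6.5]), (0, 0, 1))):
        add(nm, "C", 1, "LIG", xyz)
    add("C7", "C", 1, "LIG", (20.0, 0.0, 6.5))
    add("O1", "O", 1, "LIG", (8.0, -8.0, 0.0))
    add("H1", "H", 1, "LIG", (8.8, -8.4, 0.0))
    add("O2", "O", 1, "LIG", (-1.9, 7.04, 0.0))  # static bridge acceptor

    names = [a[0] for a in atoms]
    base = np.array([a[4] for a in atoms])
    topology = Topology(
        atom_id=np.arange(1, len(atoms) + 1),
        name=names,
        element=[a[1] for a in atoms],
        residue_number=[a[2] for a in atoms],
        residue_name=[a[3] for a in atoms],
        chain=["A"] * len(atoms),
    )
    assign_roles(topology)
    lig_ring = [int(topology.atom_id[i]) for i, a in enumerate(atoms)
                if a[3] == "LIG" and a[0] in ("C1", "C2", "C3", "C4", "C5", "C6")]
    topology.rings.append(lig_ring)
    aromatic = topology.roles["aromatic_ring_member"].copy()
    aromatic[topology.index_of(lig_ring)] = True
    topology.roles["aromatic_ring_member"] = aromatic
    topology.validate()

    def row(resnum, name):
        return int(np.where((topology.residue_number == resnum)
                            & (topology.name == name))[0][0])

    # --- qualifying geometries per kind (moving-atom coordinates)
    def hbond_coords(g):
        d = g.get("distance", 2.0)
        don_ang = g.get("donor_angle", 165.0)
        acc_ang = g.get("acceptor_angle", 120.0)
        a = base[row(10, "OE1")]
        # H in the xy-plane at the acceptor angle from the OE1->CD bond
        x_dir = (base[row(10, "CD")] - a)
        x_dir /= np.linalg.norm(x_dir)
        h_dir = _rotate_about((0, 0, 1.0), acc_ang) @ x_dir
        H = a + d * h_dir
        # donor O at 0.97 A from H, making the donor angle D-H...A
        ha = (a - H) / np.linalg.norm(a - H)
        o_dir = _rotate_about((0, 0, 1.0), don_ang) @ ha
        O = H + 0.97 * o_dir
        return {row(1, "O1"): O, row(1, "H1"): H}

    def hydrophobic_coords(g):
        d = g.get("distance", 3.4)
        p = base[row(11, "CD1")]
        return {row(1, "C7"): p + np.array([0.0, 0.0, d])}

    def pipi_coords(g):
        d = g.get("distance", 3.8)
        tilt = g.get("plane_angle", 0.0)
        center = np.array([0.0, 22.0, d])
        normal = _rotate_about((1.0, 0, 0), tilt) @ np.array([0.0, 0.0, 1.0])
        hexa = _hexagon(center, normal)
        return {row(1, nm): hexa[i] for i, nm in enumerate(("C1", "C2", "C3", "C4", "C5", "C6"))}

    def water_coords(g):
        p = base[row(10, "OE2")]       # protein acceptor
        q = base[row(1, "O2")]         # ligand acceptor
        # water oxygen midway (slightly out of plane); each hydrogen sits on
        # the O->acceptor segment, so both donor angles are 180 deg and each
        # H...acceptor distance is |Ow-acceptor| - 0.97 ~ 2.0 A.
        Ow = 0.5 * (p + q) + np.array([0.0, 0.0, 0.35])
        H1 = Ow + 0.97 * (p - Ow) / np.linalg.norm(p - Ow)
        H2 = Ow + 0.97 * (q - Ow) / np.linalg.norm(q - Ow)
        return {row(50, "O"): Ow, row(50, "H1"): H1, row(50, "H2"): H2}

    builders = {"hbond": hbond_coords, "hydrophobic": hydrophobic_coords,
                "pipi": pipi_coords, "water_bridge": water_coords}

    plans = []
    for spec in specs:
        k_present = int(round(spec.presence_fraction * n_frames))
        present = np.zeros(n_frames, dtype=bool)
        present[rng.permutation(n_frames)[:k_present]] = True
        plans.append((spec, present, builders[spec.kind](spec.geometry)))

    frames = []
    for k in range(n_frames):
        xyz = base.copy()
        for spec, present, placed in plans:
            for r, pos in placed.items():
                target = pos if present[k] else pos + _FAR
                if spec.jitter_sd > 0:
                    target = target + rng.normal(0.0, spec.jitter_sd, 3)
                xyz[r] = target
        frames.append(Frame(index=k, time=float(k), coordinates=xyz))
    return Trajectory(topology=topology, frames=frames, replica_id=replica_id,
                      system_label=system_label or SystemLabel(ligand="LIG"))


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def synth_energy_table(n_replicas: int, frames_per_replica: int,
                       mean: float, sd: float,
                       outlier_replicas: list[tuple[int, float]] | None = None,
                       hac: int = 20, seed: int = 0,
                       term_fractions: tuple = (0.6, 0.3, 0.1)) -> EnergyTable:
    """Replica-structured Gaussian dG stream with optional outlier replicas.

    ``outlier_replicas`` is a list of (replica index, replacement mean); the
    lipophilic/Coulomb/H-bond terms are fixed fractions of the total.
    """
    if n_replicas < 1 or frames_per_replica < 1:
        raise GeneratorError("n_replicas and frames_per_replica must be >= 1")
    outliers = dict(outlier_replicas or [])
    bad = [i for i in outliers if not 0 <= i < n_replicas]
    if bad:
        raise GeneratorError(f"outlier replica indices out of range: {bad}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicas):
        mu = outliers.get(rep, mean)
        dg = rng.normal(mu, sd, frames_per_replica)
        for fr in range(frames_per_replica):
            rows.append({"frame": fr, "replica": rep, "dg_total": dg[fr],
                         "dg_lipo": term_fractions[0] * dg[fr],
                         "dg_coulomb": term_fractions[1] * dg[fr],
                         "dg_hbond": term_fractions[2] * dg[fr]})
    return EnergyTable(records=pd.DataFrame(rows), hac=hac)
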