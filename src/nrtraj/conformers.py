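"""Ligand-conformation clustering and ligand shape properties.

Frames are first superposed on the protein backbone so ligand motion is
measured in the receptor frame; pairwise heavy-atom RMSD (no fit on the
ligand itself) feeds average-linkage hierarchical clustering cut at a fixed
height (default 1 A).  Clusters are ranked by occupancy, keeping at most
``max_clusters`` ranked clusters; the remainder is pooled under label -1.
Each cluster is represented by its medoid frame.

Shape descriptors: heavy-atom count, radius of gyration about the centroid,
and a probe-rolled (Shrake-Rupley) solvent-accessible surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import Frame, Topology, Trajectory
from .errors import GeometryError, NrtrajError
from .geometry import superpose

#: Bondi-style van der Waals radii (A) used for the surface calculation.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20}
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass
class ClusterResult:
    labels: np.ndarray          # ranked cluster id per frame (0 = largest; -1 = pooled)
    occupancies: np.ndarray     # fraction per ranked cluster, descending
    representatives: np.ndarray  # medoid frame position per ranked cluster
    n_clusters: int


@dataclass(frozen=True)
class LigandProperties:
    heavy_atom_count: int
    radius_of_gyration: float
    molecular_surface: float


def ligand_rmsd_matrix(traj: Trajectory, ligand_selection: list[int],
                       align_selection: list[int]) -> np.ndarray:
    """Pairwise ligand RMSD (A) across frames, in the receptor frame.

    Every frame is superposed onto frame 0 using ``align_selection`` (the
    protein backbone); the ligand RMSD between frames is then computed with
    no further fitting, so genuine ligand displacement is retained.
    """
    if not ligand_selection or not align_selection:
        raise GeometryError("empty selection in ligand_rmsd_matrix")
    top = traj.topology
    lig_idx = top.index_of(ligand_selection)
    ali_idx = top.index_of(align_selection)
    ref = traj.frames[0].coordinates[ali_idx]
    lig = np.empty((traj.n_frames, len(lig_idx), 3))
    for k, f in enumerate(traj.frames):
        R, t, _ = superpose(f.coordinates[ali_idx], ref)
        lig[k] = f.coordinates[lig_idx] @ R.T + t
    diff = lig[:, None, :, :] - lig[None, :, :, :]
    mat = np.sqrt(np.mean(np.sum(diff ** 2, axis=3), axis=2))
    return 0.5 * (mat + mat.T)  # exact symmetry against round-off


def cluster_trajectory(matrix: np.ndarray, cutoff: float = 1.0,
                       max_clusters: int = 5) -> ClusterResult:
    """Average-linkage clustering of a frame-distance matrix cut at ``cutoff``.

    Clusters are ranked by occupancy (ties broken by lower medoid frame);
    only the top ``max_clusters`` are ranked, the rest pooled under -1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise NrtrajError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8) or np.any(matrix < 0):
        raise NrtrajError("distance matrix must be symmetric and non-negative")
    n = matrix.shape[0]
    if n == 1:
        return ClusterResult(labels=np.zeros(1, dtype=int), occupancies=np.ones(1),
                             representatives=np.zeros(1, dtype=int), n_clusters=1)
    raw = fcluster(linkage(squareform(matrix, checks=False), method="average"),
                   t=cutoff, criterion="distance")
    clusters = {}
    for cid in np.unique(raw):
        members = np.where(raw == cid)[0]
        sub = matrix[np.ix_(members, members)]
        medoid = int(members[np.argmin(sub.sum(axis=1))])
        clusters[int(cid)] = (members, medoid)
    ranked = sorted(clusters.values(), key=lambda mc: (-len(mc[0]), mc[1]))
    kept = ranked[:max_clusters]
    labels = np.full(n, -1, dtype=int)
    occ, reps = [], []
    for rank, (members, medoid) in enumerate(kept):
        labels[members] = rank
        occ.append(len(members) / n)
        reps.append(medoid)
    return ClusterResult(labels=labels, occupancies=np.asarray(occ),
                         representatives=np.asarray(reps, dtype=int),
                         n_clusters=len(kept))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(coords: np.ndarray, elements, probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_points: int = DEFAULT_SPHERE_POINTS) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Each atom is expanded by the probe radius and sampled with a fixed
    golden-spiral point set; a point is accessible when outside every other
    expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(str(e).upper(), 1.7) for e in elements]) + probe_radius
    unit = _sphere_points(n_points)
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) >= radii[i] + radii[j]:
                continue
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        total += 4 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def ligand_properties(frame: Frame, topology: Topology,
                      ligand_selection: list[int],
                      probe_radius: float = DEFAULT_PROBE_RADIUS,
                      n_points: int = DEFAULT_SPHERE_POINTS) -> LigandProperties:
    """Heavy-atom count, radius of gyration and SASA for a ligand selection."""
    if not ligand_selection:
        raise GeometryError("empty ligand selection")
    idx = topology.index_of(ligand_selection)
    if (topology.element[idx] == "H").any():
        raise GeometryError("ligand_properties expects a heavy-atom selection")
    xyz = frame.coordinates[idx]
    centroid = xyz.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((xyz - centroid) ** 2, axis=1))))
    surface = sasa(xyz, topology.element[idx], probe_radius, n_points)
    return LigandProperties(heavy_atom_count=len(idx), radius_of_gyration=rg,
                            molecular_surface=surface)
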