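"""Helix-axis geometry: inter-helix angles, COM distances, RMSD, RMSF.

A helix axis is the segment between two points, each the centroid of four
consecutive C-alpha atoms at either end of the helix's residue span.  Two
angles monitor the mobile activation helix (H12): Ang1, the vertex angle at
the H10/H12 inflection point between a reference point on H3b and the H12
axis end, computed by the law of cosines on the three pairwise C-alpha
centroid distances; and Ang2, the angle between the H12 and H10 axis
vectors.  "Center of mass" is computed with unit masses (a centroid): the
point sets are C-alpha-only or whole-span selections where mass weighting is
immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import Frame, ResidueSpan, Topology, Trajectory, select_atoms
from .errors import GeometryError

#: Axes shorter than this are considered degenerate (A).
DEGENERATE_AXIS_LENGTH = 0.1

#: Shipped receptor anchor spans (UniProt numbering: ERalpha P03372, GR P04150).
DEFAULT_ANCHOR_TABLE = {
    "ERalpha": {"h3b": (348, 362), "h10": (518, 532), "h12": (538, 544)},
    "GR": {"h3b": (556, 579), "h10": (727, 740), "h12": (751, 764)},
}


@dataclass(frozen=True)
class HelixAnchors:
    """Receptor-specific residue spans for the H3b, H10 and H12 vectors."""

    receptor: str
    h3b: ResidueSpan
    h10: ResidueSpan
    h12: ResidueSpan

    def __post_init__(self) -> None:
        spans = [self.h3b, self.h10, self.h12]
        for s in spans:
            if len(s) < 4:
                raise GeometryError(f"{self.receptor}: span {s} shorter than 4 residues")
        for i, a in enumerate(spans):
            for b in spans[i + 1:]:
                if a.chain == b.chain and not (
                    a.last_residue < b.first_residue or b.last_residue < a.first_residue
                ):
                    raise GeometryError(f"{self.receptor}: overlapping spans {a} / {b}")


def default_anchors(receptor: str, chain: str = "A") -> HelixAnchors:
    """Shipped anchors for a named receptor (``ERalpha`` or ``GR``)."""
    try:
        table = DEFAULT_ANCHOR_TABLE[receptor]
    except KeyError:
        raise GeometryError(f"no shipped anchors for receptor '{receptor}'") from None
    return HelixAnchors(
        receptor=receptor,
        **{k: ResidueSpan(chain, lo, hi) for k, (lo, hi) in table.items()},
    )


@dataclass(frozen=True)
class HelixAxis:
    """Axis segment from the centroid of the first four C-alphas to the last four."""

    start_point: np.ndarray
    end_point: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return self.end_point - self.start_point

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.vector))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start_point + self.end_point)


def _span_calpha_coords(frame: Frame, topology: Topology, span: ResidueSpan) -> np.ndarray:
    """C-alpha coordinates of a span, ordered by residue number."""
    ids = select_atoms(topology, span=span, role="c_alpha")
    idx = topology.index_of(ids)
    order = np.argsort(topology.residue_number[idx], kind="stable")
    return frame.coordinates[idx[order]]


def helix_axis(frame: Frame, topology: Topology, span: ResidueSpan) -> HelixAxis:
    """Helix axis of a residue span in one frame.

    The start/end points are centroids of the first/last four C-alpha atoms
    taken in increasing residue-number order; the span must resolve to at
    least 8 C-alphas and the resulting segment must be longer than 0.1 A.
    """
    ca = _span_calpha_coords(frame, topology, span)
    if ca.shape[0] < 8:
        raise GeometryError(
            f"span {span} has {ca.shape[0]} C-alpha atoms; helix axis needs >= 8"
        )
    start = ca[:4].mean(axis=0)
    end = ca[-4:].mean(axis=0)
    if np.linalg.norm(end - start) <= DEGENERATE_AXIS_LENGTH:
        raise GeometryError(f"degenerate axis for span {span} (length <= 0.1 A)")
    return HelixAxis(start_point=start, end_point=end)


def axis_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle between two helix axes in degrees, in [0, 180]; symmetric."""
    va, vb = a.vector, b.vector
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na <= DEGENERATE_AXIS_LENGTH or nb <= DEGENERATE_AXIS_LENGTH:
        raise GeometryError("degenerate axis in axis_angle")
    cos = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def vertex_angle(p: np.ndarray, vertex: np.ndarray, q: np.ndarray) -> float:
    """Angle at ``vertex`` between ``p`` and ``q``, by the law of cosines.

    Computed from the three pairwise Euclidean distances and clamped to
    [0, 180] against round-off.
    """
    p, vertex, q = (np.asarray(x, dtype=float) for x in (p, vertex, q))
    a = np.linalg.norm(p - vertex)
    b = np.linalg.norm(q - vertex)
    if a <= 1e-12 or b <= 1e-12:
        raise GeometryError("zero-length arm in vertex_angle")
    c = np.linalg.norm(p - q)
    cos = np.clip((a * a + b * b - c * c) / (2 * a * b), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 <= 1e-12:
        raise GeometryError("degenerate central bond in dihedral")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class AngleSeries:
    """Per-frame Ang1/Ang2 (degrees)."""

    ang1: np.ndarray
    ang2: np.ndarray


def angle_series(traj: Trajectory, anchors: HelixAnchors) -> AngleSeries:
    """Per-frame Ang1 and Ang2 for a trajectory.

    Ang1 is the vertex angle at the H10/H12 inflection point (end of the H10
    axis) between the H3b axis midpoint and the H12 axis end; Ang2 is the
    angle between the H12 and H10 axis vectors.  These anchor-point choices
    are one convention for monitoring H12 displacement; change the anchors
    object to probe others.
    """
    top = traj.topology
    ang1 = np.empty(traj.n_frames)
    ang2 = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        try:
            ax3b = helix_axis(frame, top, anchors.h3b)
            ax10 = helix_axis(frame, top, anchors.h10)
            ax12 = helix_axis(frame, top, anchors.h12)
            vertex = ax10.end_point
            ang1[k] = vertex_angle(ax3b.midpoint, vertex, ax12.end_point)
            ang2[k] = axis_angle(ax12, ax10)
        except GeometryError as exc:
            raise GeometryError(f"frame {frame.index}: {exc}") from exc
    return AngleSeries(ang1=ang1, ang2=ang2)


@dataclass
class DistanceSeries:
    """Per-frame centroid distance between two residue spans (A)."""

    pair_label: str
    values: np.ndarray


def com_distance_series(traj: Trajectory, span_a: ResidueSpan, span_b: ResidueSpan,
                        pair_label: str | None = None) -> DistanceSeries:
    """Per-frame distance between the centroids of all atoms of two spans."""
    top = traj.topology
    ids_a = select_atoms(top, span=span_a)
    ids_b = select_atoms(top, span=span_b)
    if not ids_a or not ids_b:
        raise GeometryError(f"empty span in distance request: {span_a} / {span_b}")
    ia, ib = top.index_of(ids_a), top.index_of(ids_b)
    coords = traj.coordinates()
    coma = coords[:, ia].mean(axis=1)
    comb = coords[:, ib].mean(axis=1)
    values = np.linalg.norm(coma - comb, axis=1)
    if pair_label is None:
        pair_label = (f"{span_a.first_residue}-{span_a.last_residue}__"
                      f"{span_b.first_residue}-{span_b.last_residue}")
    return DistanceSeries(pair_label=pair_label, values=values)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix, translation, transformed mobile coordinates);
    apply to any other coordinate set as ``x @ R.T + t``.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t, mobile @ R.T + t


def rmsd(reference: Frame, frame: Frame, selection: list[int],
         topology: Topology, superpose_first: bool = True) -> float:
    """RMSD over a selection, optionally after least-squares superposition."""
    if not selection:
        raise GeometryError("empty selection in rmsd")
    idx = topology.index_of(selection)
    ref = reference.coordinates[idx]
    mob = frame.coordinates[idx]
    if superpose_first:
        _, _, mob = superpose(mob, ref)
    return float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))


def superpose_trajectory(traj: Trajectory, selection: list[int]) -> Trajectory:
    """New trajectory with every frame superposed onto frame 0 on ``selection``."""
    if not selection:
        raise GeometryError("empty selection in superpose_trajectory")
    idx = traj.topology.index_of(selection)
    ref = traj.frames[0].coordinates[idx]
    frames = []
    for f in traj.frames:
        R, t, _ = superpose(f.coordinates[idx], ref)
        frames.append(Frame(index=f.index, time=f.time,
                            coordinates=f.coordinates @ R.T + t))
    return Trajectory(topology=traj.topology, frames=frames,
                      replica_id=traj.replica_id, system_label=traj.system_label)


def rmsf(traj: Trajectory, selection: list[int]) -> pd.Series:
    """Per-atom RMSF (A) about the time-average position, indexed by residue.

    The caller is responsible for aligning frames first (see
    :func:`superpose_trajectory`); requires at least two frames.  The index
    is the residue number of each selected atom, so a C-alpha selection gives
    a per-residue profile.
    """
    if traj.n_frames < 2:
        raise GeometryError("rmsf needs at least 2 frames")
    if not selection:
        raise GeometryError("empty selection in rmsf")
    idx = traj.topology.index_of(selection)
    coords = traj.coordinates()[:, idx]           # (F, S, 3)
    mean = coords.mean(axis=0, keepdims=True)
    fluct = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    resnum = traj.topology.residue_number[idx]
    return pd.Series(fluct, index=pd.Index(resnum, name="residue"), name="rmsf")


def series_frame(traj: Trajectory, metric: str, values: np.ndarray) -> pd.DataFrame:
    """Tidy per-frame series: system label, replica, frame, metric, value."""
    lab = traj.system_label
    return pd.DataFrame({
        "receptor": lab.receptor,
        "ligand": lab.ligand,
        "start_conformation": lab.start_conformation,
        "replica": traj.replica_id,
        "frame": [f.index for f in traj.frames],
        "metric": metric,
        "value": np.asarray(values, dtype=float),
    })
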