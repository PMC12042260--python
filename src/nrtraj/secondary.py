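"""Per-residue helicity assignment and span-level folded fraction (SSE%).

A residue is called helical when its backbone dihedrals sit in the alpha
region — phi in [-100, -30] and psi in [-80, -5] degrees — and at least one
flanking residue does too (a lone alpha-region residue is not a helix turn).
Terminal residues of a span, which lack one dihedral, inherit the state of
their single neighbour.  When backbone N/C atoms are absent a C-alpha-only
fallback is used: the virtual dihedral over C-alpha(i-1..i+2), which is
40-70 degrees in an alpha helix.

The window bounds are deliberately plain constants rather than tunables: the
readout is a coarse folded/unfolded dichotomy for the mobile activation
helix, not a full secondary-structure taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, ResidueSpan, Topology, Trajectory, select_atoms
from .errors import GeometryError
from .geometry import dihedral_angle

PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)
CA_VIRTUAL_WINDOW = (40.0, 70.0)


@dataclass
class HelicitySeries:
    """Folded-fraction series for one span: per-frame and per-residue."""

    span: ResidueSpan
    per_frame_fraction: np.ndarray   # (n_frames,), in [0, 1]
    per_residue_fraction: np.ndarray  # (span length,), in [0, 1]

    @property
    def mean_fraction(self) -> float:
        return float(self.per_frame_fraction.mean())


def _backbone_positions(frame: Frame, topology: Topology, span: ResidueSpan,
                        names: tuple[str, ...]):
    """Per-residue dict name -> coordinate for the span, or None where absent."""
    out = []
    for resnum in span.residues():
        entry = {}
        for nm in names:
            ids = select_atoms(topology, chain=span.chain, residue_number=resnum, name=nm)
            entry[nm] = frame.coordinates[topology.index_of(ids[0])[0]] if ids else None
        out.append(entry)
    return out


def assign_helicity(frame: Frame, topology: Topology, span: ResidueSpan) -> np.ndarray:
    """Boolean helicity per residue of ``span`` in one frame.

    Uses phi/psi windows when backbone N/CA/C atoms are present for the span,
    otherwise the C-alpha virtual-dihedral fallback.  Spans shorter than 4
    residues are rejected.
    """
    nres = len(span)
    if nres < 4:
        raise GeometryError(f"helicity assignment needs a span of >= 4 residues, got {nres}")
    bb = _backbone_positions(frame, topology, span, ("N", "CA", "C"))
    if any(e["CA"] is None for e in bb):
        raise GeometryError(f"span {span}: missing C-alpha atom(s)")
    full_backbone = all(e["N"] is not None and e["C"] is not None for e in bb)

    in_alpha = np.zeros(nres, dtype=bool)
    defined = np.zeros(nres, dtype=bool)
    if full_backbone:
        for i in range(1, nres - 1):
            phi = dihedral_angle(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
            psi = dihedral_angle(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
            in_alpha[i] = (PHI_WINDOW[0] <= phi <= PHI_WINDOW[1]
                           and PSI_WINDOW[0] <= psi <= PSI_WINDOW[1])
            defined[i] = True
    else:  # C-alpha fallback: virtual dihedral CA(i-1), CA(i), CA(i+1), CA(i+2)
        ca = [e["CA"] for e in bb]
        for i in range(1, nres - 2):
            vd = dihedral_angle(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
            in_alpha[i] = CA_VIRTUAL_WINDOW[0] <= vd <= CA_VIRTUAL_WINDOW[1]
            defined[i] = True

    helical = np.zeros(nres, dtype=bool)
    interior = np.where(defined)[0]
    for i in interior:
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < nres and defined[j]]
        flank_ok = any(in_alpha[j] for j in neighbours) if neighbours else True
        helical[i] = in_alpha[i] and flank_ok
    # terminal residues inherit their single defined neighbour's state
    if len(interior):
        for i in range(interior[0]):
            helical[i] = helical[interior[0]]
        for i in range(interior[-1] + 1, nres):
            helical[i] = helical[interior[-1]]
    return helical


def sse_fraction(traj: Trajectory, span: ResidueSpan) -> HelicitySeries:
    """Folded fraction of a span over a trajectory (per frame and per residue)."""
    per_res_count = np.zeros(len(span))
    per_frame = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        helical = assign_helicity(frame, traj.topology, span)
        per_frame[k] = helical.mean()
        per_res_count += helical
    return HelicitySeries(span=span, per_frame_fraction=per_frame,
                          per_residue_fraction=per_res_count / traj.n_frames)
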