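"""Role-flag assignment from residue/atom templates.

The upstream interaction-analysis tooling the field uses assigns donor,
acceptor and hydrophobic types internally; here the assignment is an explicit
table so it is inspectable and testable.  Protein flags come from a
per-residue template keyed on standard PDB atom names; ligand and water atoms
are typed by element (N/O heavy atoms are treated as both potential donors —
when they carry a hydrogen — and acceptors).
"""

from __future__ import annotations

import numpy as np

from .core import Topology

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain heavy atoms that can donate an H-bond (carry at least one H).
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

# Side-chain heavy atoms that can accept an H-bond.
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

# Aromatic ring atom names for the standard aromatic residues.
AROMATIC_RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}

# Residues whose side-chain carbons count as hydrophobic contacts.
HYDROPHOBIC_RESIDUES = {
    "ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR", "CYS",
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def assign_roles(topology: Topology) -> None:
    """Populate role flags on ``topology`` in place from the template table.

    Ligand atoms are the HETATM-style residues that are neither water nor a
    standard amino acid.  Aromatic rings for PHE/TYR/TRP/HIS are registered in
    ``topology.rings``; ligand rings must be registered by the caller (the
    synthetic generators do so) because ring perception needs connectivity.
    """
    n = topology.n_atoms
    elem = topology.element
    name = topology.name
    resname = topology.residue_name

    is_water = np.isin(resname, sorted(WATER_RESNAMES))
    is_protein = np.isin(resname, sorted(STANDARD_AA))
    is_ligand = ~is_water & ~is_protein

    heavy = elem != "H"
    c_alpha = is_protein & (name == "CA") & (elem == "C")
    backbone = is_protein & np.isin(name, sorted(_BACKBONE_NAMES)) & heavy

    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    hydrophobic = np.zeros(n, dtype=bool)
    for i in range(n):
        rn, an, el = resname[i], name[i], elem[i]
        if is_water[i]:
            if el == "O":
                donor[i] = True
                acceptor[i] = True
        elif is_protein[i]:
            if an == "N" and rn != "PRO":
                donor[i] = True
            if an in ("O", "OXT"):
                acceptor[i] = True
            if an in _SIDECHAIN_DONORS.get(rn, ()):
                donor[i] = True
            if an in _SIDECHAIN_ACCEPTORS.get(rn, ()):
                acceptor[i] = True
            if el == "C" and rn in HYDROPHOBIC_RESIDUES and an not in _BACKBONE_NAMES:
                hydrophobic[i] = True
        else:  # ligand: element-typed
            if el in ("N", "O"):
                donor[i] = True  # validated against attached H at detection time
                acceptor[i] = True
            if el == "C":
                hydrophobic[i] = True

    topology.roles["heavy"] = heavy
    topology.roles["c_alpha"] = c_alpha
    topology.roles["backbone"] = backbone
    topology.roles["ligand"] = is_ligand
    topology.roles["water"] = is_water
    topology.roles["hbond_donor_heavy"] = donor & heavy
    topology.roles["hbond_acceptor"] = acceptor & heavy
    topology.roles["hydrophobic_carbon"] = hydrophobic

    aromatic = np.zeros(n, dtype=bool)
    rings: list[list[int]] = list(topology.rings)
    seen = {tuple(r) for r in rings}
    for (ch, rnum) in {(topology.chain[i], topology.residue_number[i])
                       for i in range(n) if is_protein[i]}:
        sel = (topology.chain == ch) & (topology.residue_number == rnum)
        rn = resname[np.argmax(sel)]
        ring_names = AROMATIC_RING_ATOMS.get(rn)
        if not ring_names:
            continue
        ring_ids = []
        for rname in ring_names:
            hit = sel & (name == rname)
            if hit.any():
                ring_ids.append(int(topology.atom_id[np.argmax(hit)]))
        if len(ring_ids) >= 5 and tuple(ring_ids) not in seen:
            rings.append(ring_ids)
            seen.add(tuple(ring_ids))
    for ring in rings:
        aromatic[topology.index_of(ring)] = True
    topology.rings = rings
    topology.roles["aromatic_ring_member"] = aromatic
    topology.validate()
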