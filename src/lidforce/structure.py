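"""Structural cross-check: attachment-point distance change on lid closing.

The DNA handles attach at cysteines inserted after residues 42 and 144;
crystal structures of the open (PDB 2RH5) and closed, inhibitor-bound
(PDB 2RGX) conformations predict a Cα–Cα distance change between the
attachment residues of about 1.7 nm.  This module computes that change
from locally available PDB files (they are not bundled and must be
supplied by the user).
"""

from __future__ import annotations

import numpy as np


def ca_distance(pdb_path, residue_a: int, residue_b: int, chain: str | None = None) -> float:
    """Cα–Cα distance (nm) between two residues of a PDB file."""
    import gemmi

    structure = gemmi.read_structure(str(pdb_path))
    structure.setup_entities()
    model = structure[0]
    coords = {}
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num in (residue_a, residue_b):
                ca = res.find_atom("CA", "*")
                if ca is not None and res.seqid.num not in coords:
                    coords[res.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    missing = {residue_a, residue_b} - set(coords)
    if missing:
        raise ValueError(f"{pdb_path}: no Cα found for residues {sorted(missing)}")
    return float(np.linalg.norm(coords[residue_a] - coords[residue_b])) / 10.0


def attachment_distance_change(
    pdb_open,
    pdb_closed,
    residue_a: int = 42,
    residue_b: int = 144,
    chain: str | None = None,
) -> float:
    """Distance change (nm) between attachment residues, open − closed.

    Positive when the open conformation is more extended; ~1.7 nm for
    the adenylate kinase open/closed pair.
    """
    d_open = ca_distance(pdb_open, residue_a, residue_b, chain)
    d_closed = ca_distance(pdb_closed, residue_a, residue_b, chain)
    return d_open - d_closed
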