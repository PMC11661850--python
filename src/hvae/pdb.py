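"""Optional PDB reader: residue-centered atomic neighborhoods as labeled
point clouds.

Each neighborhood is centered at a residue's C-alpha, contains the heavy
atoms (C, N, O, S; hydrogens and other elements excluded) within ``r_max``
of that center, and stores coordinates relative to the center.  The core
transforms never require this module.
"""

from __future__ import annotations

import numpy as np
from Bio.PDB import PDBParser

from .transforms import DEFAULT_CHANNELS, LabeledPointCloud

__all__ = ["residue_neighborhoods"]


def residue_neighborhoods(
    path,
    r_max: float = 10.0,
    elements: tuple[str, ...] = DEFAULT_CHANNELS,
) -> list[tuple[str, LabeledPointCloud]]:
    """Extract (residue-id, neighborhood cloud) pairs from a PDB file.

    Residues without a C-alpha atom (waters, most hetero groups) are
    skipped as centers but their atoms still contribute to neighborhoods.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    atoms = []
    for atom in structure.get_atoms():
        el = (atom.element or "").upper()
        if el in elements:
            atoms.append((el, atom.coord.astype(float)))
    if not atoms:
        return []
    labels = np.array([a[0] for a in atoms], dtype=object)
    coords = np.array([a[1] for a in atoms])
    out = []
    for residue in structure.get_residues():
        if "CA" not in residue:
            continue
        center = residue["CA"].coord.astype(float)
        rel = coords - center
        mask = np.linalg.norm(rel, axis=1) <= r_max
        chain = residue.get_parent().id
        res_id = f"{chain}:{residue.get_resname()}{residue.id[1]}"
        out.append((res_id, LabeledPointCloud(rel[mask], tuple(labels[mask]))))
    return out
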