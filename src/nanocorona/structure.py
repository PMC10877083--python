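"""Coarse-graining of protein structures: one bead per residue.

Beads are placed at the centroid of the side-chain heavy atoms (the alpha
carbon for glycine), typed by the three-letter residue code, with the mass
summed over the residue's heavy atoms — matching the convention of the
side-chain-analogue PMFs that parameterise the short-range potentials.
Residue charges default to the standard values at pH 7.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

from .cg_model import BeadSpec, CGMolecule

__all__ = ["read_structure", "AMINO_ACID_BEADS", "RESIDUE_CHARGES"]

log = logging.getLogger(__name__)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

# Net side-chain charge (e) at pH 7; unlisted residues are neutral.
RESIDUE_CHARGES = {"ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0, "HIS": 0.0}

# Residue masses (Da, average residue mass within a chain) and bead radii
# (nm, roughly the side-chain-analogue van der Waals extent).
_RESIDUE_MASS = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}
_RESIDUE_RADIUS = {
    "ALA": 0.25, "ARG": 0.41, "ASN": 0.32, "ASP": 0.30, "CYS": 0.29,
    "GLN": 0.35, "GLU": 0.33, "GLY": 0.23, "HIS": 0.35, "ILE": 0.34,
    "LEU": 0.34, "LYS": 0.38, "MET": 0.36, "PHE": 0.38, "PRO": 0.30,
    "SER": 0.26, "THR": 0.29, "TRP": 0.42, "TYR": 0.39, "VAL": 0.31,
}

AMINO_ACID_BEADS = tuple(
    BeadSpec(bead_type=code, charge=RESIDUE_CHARGES.get(code, 0.0),
             radius=_RESIDUE_RADIUS[code], mass=_RESIDUE_MASS[code])
    for code in sorted(_RESIDUE_MASS)
)


class StructureFormatError(ValueError):
    """Raised when a structure file yields no usable residues."""


def _first_altloc(atom):
    """First altloc wins for disordered atoms."""
    if atom.is_disordered():
        children = atom.disordered_get_list()
        return sorted(children, key=lambda a: a.get_altloc())[0]
    return atom


def read_structure(path, name: str | None = None,
                   bulk_concentration: float = 0.0) -> CGMolecule:
    """Coarse-grain a PDB file into one bead per residue.

    Only ATOM records contribute (HETATM residues are ignored); hydrogens are
    skipped; unknown residues are skipped with a logged warning.  Raises
    :class:`StructureFormatError` when no residues survive.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(name or path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureFormatError(f"{path}: no models in file") from None

    bead_types, positions, masses, charges = [], [], [], []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag.strip():
                continue  # HETATM / water
            resname = residue.get_resname().strip()
            if resname not in _RESIDUE_MASS:
                if is_aa(residue, standard=False):
                    log.warning("skipping unknown residue %s in %s", resname, path)
                continue
            heavy = [
                _first_altloc(a) for a in residue.get_atoms()
                if (a.element or "").strip().upper() != "H"
            ]
            if not heavy:
                continue
            side = [a for a in heavy if a.get_name() not in _BACKBONE]
            anchor = side if (side and resname != "GLY") else [
                a for a in heavy if a.get_name() == "CA"
            ]
            if not anchor:
                anchor = heavy
            centroid = np.mean([a.get_coord() for a in anchor], axis=0) / 10.0  # A -> nm
            bead_types.append(resname)
            positions.append(centroid)
            masses.append(_RESIDUE_MASS[resname])
            charges.append(RESIDUE_CHARGES.get(resname, 0.0))

    if not bead_types:
        raise StructureFormatError(f"{path}: no ATOM records with known residues")
    return CGMolecule(
        name=name or path.stem,
        bead_types=tuple(bead_types),
        positions=np.array(positions),
        masses=np.array(masses),
        charges=np.array(charges),
        molecular_weight=float(np.sum(masses)) + 18.02,  # + terminal water
        bulk_concentration=bulk_concentration,
    )
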