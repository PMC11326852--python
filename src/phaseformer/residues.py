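"""Idealized amino-acid residue templates.

Templates are the standardized, example-independent conformations used both
to build partial-structure maps and to grow synthetic peptide chains. They
come from the Chemical Component Dictionary bundled with biotite (idealized
coordinates), with chain-terminal atoms (OXT and its hydrogens) stripped so
a template represents a mid-chain residue.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from biotite.structure.info import residue as _ccd_residue

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Atoms that only exist at chain termini in the CCD monomers.
_TERMINAL_ATOMS = {"OXT", "HXT", "H2", "H3"}


class UnsupportedResidueError(KeyError):
    pass


@lru_cache(maxsize=None)
def _template_arrays(res_type: str, include_hydrogens: bool):
    if res_type not in STANDARD_RESIDUES:
        raise UnsupportedResidueError(
            f"residue {res_type!r} is not one of the 20 standard amino acids")
    try:
        arr = _ccd_residue(res_type)
    except Exception as exc:  # biotite raises KeyError subclasses
        raise UnsupportedResidueError(f"no template for residue {res_type!r}") from exc
    if arr is None:
        raise UnsupportedResidueError(f"no template for residue {res_type!r}")
    keep = ~np.isin(arr.atom_name, list(_TERMINAL_ATOMS))
    if not include_hydrogens:
        keep &= arr.element != "H"
    arr = arr[keep]
    names = tuple(arr.atom_name)
    elements = tuple(e.capitalize() for e in arr.element)
    coords = np.array(arr.coord, dtype=float)
    coords.setflags(write=False)
    return names, elements, coords


def get_template(res_type: str, include_hydrogens: bool = False):
    """Return (atom_names, elements, coords) for an idealized residue.

    Coordinates are Cartesian A in the CCD's arbitrary frame; callers
    recenter or superimpose as needed. Raises UnsupportedResidueError for
    residue types without a template.
    """
    names, elements, coords = _template_arrays(res_type.upper(), include_hydrogens)
    return list(names), list(elements), coords.copy()


def backbone_indices(atom_names: list[str]) -> tuple[int, int, int]:
    """Indices of N, CA, C in an atom-name list."""
    try:
        return atom_names.index("N"), atom_names.index("CA"), atom_names.index("C")
    except ValueError as exc:
        raise UnsupportedResidueError("template lacks backbone atoms N/CA/C") from exc
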