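"""Turn peptide fragments into (Patterson, density, partial-structure) examples.

The construction rules emulate a crystalline training-set recipe: each
fragment gets its own orthorhombic P1 cell (either expanded from the
coordinate ranges until periodic neighbours are at least 2.75 A away, or a
fixed cell), axes are reindexed longest-to-shortest, the molecule is
centered by mass in the cell (removing the translation ambiguity that the
Patterson map cannot resolve), and density / Patterson / per-residue
partial-structure maps are synthesized and normalized to [-1, 1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import residues as _res
from .xtal import (
    Atom,
    FragmentStructure,
    GridSpec,
    UnitCell,
    VolumeGrid,
    build_grid,
    calc_structure_factors,
    density_from_sf,
    normalize_map,
    patterson_from_sf,
)

__all__ = [
    "BuilderConfig",
    "ExampleRecord",
    "PartialStructureSet",
    "DiscardedExample",
    "min_intermolecular_contact",
    "expand_cell",
    "center_structure",
    "reindex_axes",
    "make_partial_structures",
    "bin_and_filter",
    "place_structure",
    "build_example",
]

CONTACT_THRESHOLD = 2.75  # A, minimum allowed intermolecular atomic contact
FIXED_CELL_15MER = (41.0, 30.0, 24.0)  # A, fixed cell for 15-residue fragments


class DiscardedExample(Exception):
    """Raised when a fragment cannot become a valid example.

    ``reason`` is a short machine-readable code ("clash",
    "expansion_exhausted", ...).
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class PartialStructureSet:
    """Ordered per-residue standalone density grids conditioning the model."""

    grids: list[VolumeGrid]

    def __len__(self) -> int:
        return len(self.grids)

    def as_array(self) -> np.ndarray:
        """Stack to shape (J, N1, N2, N3)."""
        return np.stack([g.values for g in self.grids]) if self.grids else np.empty((0,))


@dataclass
class ExampleRecord:
    """One training example: Patterson input, density target, partials."""

    id: str
    patterson: VolumeGrid
    density: VolumeGrid
    partials: PartialStructureSet
    cell: UnitCell
    n_residues: int
    residue_types: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.patterson.dims


@dataclass
class BuilderConfig:
    """Dataset-construction settings.

    mode "variable_cell" grows a per-fragment minimal cell; "fixed_cell"
    places every fragment in ``fixed_cell`` (defaults to the 41x30x24 A
    cell used for 15-mers) and discards fragments that clash there.
    """

    d_min: float = 1.5
    oversampling: float = 3.0
    contact_threshold: float = CONTACT_THRESHOLD
    mode: str = "variable_cell"
    fixed_cell: tuple[float, float, float] = FIXED_CELL_15MER
    expand_step: float = 0.25
    max_expand_iter: int = 100
    min_batch: int = 1
    scattering_model: str = "point"
    include_hydrogens: bool = True
    partial_placement: str = "centered"  # or "true"
    pad_to_multiple: tuple[int, int, int] | None = None


_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)],
    dtype=float,
)


def min_intermolecular_contact(structure: FragmentStructure) -> float:
    """Minimum distance from the central copy to the 26 neighbouring images.

    Pairs within the central copy (zero lattice offset) are excluded, so
    intramolecular geometry does not affect the result.
    """
    if not structure.atoms:
        raise ValueError("structure has no atoms")
    pos = structure.wrapped().positions
    shifts = _NEIGHBOR_OFFSETS * structure.cell.edges
    best = np.inf
    for shift in shifts:
        diff = pos[:, None, :] - (pos[None, :, :] + shift)
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        best = min(best, float(np.sqrt(d2.min())))
    return best


def expand_cell(
    structure: FragmentStructure,
    threshold: float = CONTACT_THRESHOLD,
    step: float = 0.25,
    max_iter: int = 100,
    initial_cell: UnitCell | None = None,
) -> FragmentStructure:
    """Grow the cell until periodic copies are at least ``threshold`` apart.

    The starting cell is the per-axis coordinate range (max - min) unless
    ``initial_cell`` is given; all three axes grow by ``step`` each
    iteration. Atoms keep their Cartesian positions (re-wrapped). Raises
    DiscardedExample("expansion_exhausted") after ``max_iter`` iterations.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pos = structure.positions
    if initial_cell is None:
        ranges = pos.max(axis=0) - pos.min(axis=0)
        edges = np.maximum(ranges, step)
    else:
        edges = initial_cell.edges
    # shift so the fragment starts at the origin of its bounding box
    pos = pos - pos.min(axis=0)
    for _ in range(max_iter + 1):
        candidate = structure.with_positions(pos, UnitCell(*edges))
        if min_intermolecular_contact(candidate) >= threshold:
            return candidate.wrapped()
        edges = edges + step
    raise DiscardedExample("expansion_exhausted",
                           f"no contact >= {threshold} A within {max_iter} steps")


def center_structure(structure: FragmentStructure) -> FragmentStructure:
    """Translate all atoms so the center of mass sits at (a/2, b/2, c/2)."""
    pos = structure.positions
    masses = structure.masses()
    com = masses @ pos / masses.sum()
    shift = structure.cell.edges / 2.0 - com
    return structure.with_positions(pos + shift)


def reindex_axes(structure: FragmentStructure) -> FragmentStructure:
    """Permute axes so a >= b >= c, longest first; ties keep original order."""
    edges = structure.cell.edges
    perm = np.argsort(-edges, kind="stable")
    new_edges = edges[perm]
    new_pos = structure.positions[:, perm]
    return structure.with_positions(new_pos, UnitCell(*new_edges))


def _template_structure(res_type: str, cell: UnitCell,
                        include_hydrogens: bool) -> FragmentStructure:
    names, elements, coords = _res.get_template(res_type, include_hydrogens)
    atoms = [Atom(el, xyz) for el, xyz in zip(elements, coords)]
    frag = FragmentStructure(atoms, [(res_type, (0, len(atoms)))], cell)
    return center_structure(frag)


_partial_cache: dict[tuple, VolumeGrid] = {}


def make_partial_structures(
    structure: FragmentStructure,
    grid: GridSpec,
    d_min: float,
    scattering_model: str = "point",
    include_hydrogens: bool = True,
    placement: str = "centered",
) -> PartialStructureSet:
    """Standalone per-residue template densities on the example's grid.

    Each residue contributes one grid computed from the idealized template
    of its residue type, centered in the cell ("centered" placement, the
    default; templates are then identical across examples for a given
    residue type, cell and grid) or translated to the residue's own
    center of mass ("true" placement).
    """
    grids: list[VolumeGrid] = []
    cell = structure.cell
    for res_type, (start, stop) in structure.residues:
        key = (res_type, tuple(cell.edges), grid.dims, d_min,
               scattering_model, include_hydrogens)
        if placement == "centered" and key in _partial_cache:
            grids.append(_partial_cache[key])
            continue
        frag = _template_structure(res_type, cell, include_hydrogens)
        if placement == "true":
            res_atoms = structure.atoms[start:stop]
            masses = np.array([_mass(a.element) for a in res_atoms])
            target = masses @ np.array([a.position for a in res_atoms]) / masses.sum()
            frag = frag.with_positions(
                frag.positions + (target - cell.edges / 2.0))
        elif placement != "centered":
            raise ValueError(f"unknown partial placement {placement!r}")
        refs = calc_structure_factors(frag, d_min, scattering_model,
                                      include_hydrogens=include_hydrogens)
        norm = normalize_map(density_from_sf(refs, grid))
        out = norm.copy_with(norm.values, kind="partial")
        if placement == "centered":
            _partial_cache[key] = out
        grids.append(out)
    return PartialStructureSet(grids)


def _mass(element: str) -> float:
    from .xtal import ATOMIC_MASSES
    return ATOMIC_MASSES[element]


def bin_and_filter(examples: list[ExampleRecord], min_batch: int = 1):
    """Group examples by grid dims; drop bins smaller than ``min_batch``.

    Returns (bins, report): bins maps a dims triple to its examples, report
    counts kept/dropped examples and lists dropped bins.
    """
    if min_batch < 1:
        raise ValueError("min_batch must be >= 1")
    bins: dict[tuple[int, int, int], list[ExampleRecord]] = {}
    for ex in examples:
        bins.setdefault(ex.dims, []).append(ex)
    kept = {dims: exs for dims, exs in bins.items() if len(exs) >= min_batch}
    dropped = {dims: len(exs) for dims, exs in bins.items() if len(exs) < min_batch}
    report = {
        "n_kept": sum(len(v) for v in kept.values()),
        "n_dropped": sum(dropped.values()),
        "dropped_bins": {str(k): v for k, v in dropped.items()},
    }
    return kept, report


def _pad_dims(dims: tuple[int, int, int],
              multiple: tuple[int, int, int]) -> tuple[int, int, int]:
    return tuple(-(-n // m) * m for n, m in zip(dims, multiple))  # type: ignore


def _pad_grid(g: VolumeGrid, dims: tuple[int, int, int]) -> VolumeGrid:
    pad = [(0, t - n) for n, t in zip(g.dims, dims)]
    if all(p == (0, 0) for p in pad):
        return g
    return g.copy_with(np.pad(g.values, pad))


def place_structure(structure: FragmentStructure,
                    cfg: BuilderConfig) -> FragmentStructure:
    """Give a fragment its crystal cell and canonical placement.

    variable_cell: expand the cell from the coordinate ranges until the
    contact threshold holds (or discard). fixed_cell: place in
    ``cfg.fixed_cell`` and discard on clash. Axes are then reindexed
    longest-to-shortest and the mass centroid moved to the cell center.
    """
    if cfg.mode == "variable_cell":
        st = expand_cell(structure, cfg.contact_threshold, cfg.expand_step,
                         cfg.max_expand_iter)
    elif cfg.mode == "fixed_cell":
        st = structure.with_positions(structure.positions,
                                      UnitCell(*cfg.fixed_cell))
        st = center_structure(st)
        contact = min_intermolecular_contact(st)
        if contact < cfg.contact_threshold:
            raise DiscardedExample(
                "clash", f"contact {contact:.2f} A < {cfg.contact_threshold} A")
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    return center_structure(reindex_axes(st))


def build_example(
    structure: FragmentStructure,
    cfg: BuilderConfig,
    example_id: str | None = None,
) -> ExampleRecord:
    """Run the full construction pipeline on one fragment.

    Places the fragment (see place_structure), computes structure factors
    to ``d_min``, synthesizes density / Patterson / partials, and
    normalizes every map. Raises DiscardedExample on failure.
    """
    st = place_structure(structure, cfg)
    grid = build_grid(st.cell, cfg.d_min, cfg.oversampling)
    refs = calc_structure_factors(st, cfg.d_min, cfg.scattering_model,
                                  include_hydrogens=cfg.include_hydrogens)
    density = normalize_map(density_from_sf(refs, grid))
    patterson = normalize_map(patterson_from_sf(refs, grid))
    partials = make_partial_structures(
        st, grid, cfg.d_min, cfg.scattering_model,
        cfg.include_hydrogens, cfg.partial_placement)

    crystal_dims = grid.dims
    if cfg.pad_to_multiple is not None:
        target = _pad_dims(grid.dims, cfg.pad_to_multiple)
        density = _pad_grid(density, target)
        patterson = _pad_grid(patterson, target)
        partials = PartialStructureSet([_pad_grid(g, target) for g in partials.grids])

    if example_id is None:
        digest = hashlib.sha1(np.ascontiguousarray(st.positions).tobytes()).hexdigest()
        example_id = f"ex-{digest[:10]}"
    res_types = [r for r, _ in st.residues]
    return ExampleRecord(
        id=example_id,
        patterson=patterson,
        density=density,
        partials=partials,
        cell=st.cell,
        n_residues=st.n_residues,
        residue_types=res_types,
        meta={"crystal_dims": list(crystal_dims), "d_min": cfg.d_min,
              "oversampling": cfg.oversampling},
    )
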