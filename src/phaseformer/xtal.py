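"""Crystallographic math core for orthorhombic P1 cells.

Everything downstream — dataset construction, model training, evaluation —
rests on the primitives here: structure factors by direct summation over
atoms, electron-density synthesis by FFT, Patterson maps by either squared
amplitudes or density autocorrelation, map normalization, and phase-error
statistics in resolution shells.

Conventions (fixed throughout the package):

* The unit cell is orthorhombic (all angles 90 deg) with no symmetry beyond
  lattice translations (space group P1).
* Voxel ``(i, j, k)`` of an ``N1 x N2 x N3`` grid samples the cell at
  fractional coordinates ``(i/N1, j/N2, k/N3)``; the origin sits at index 0.
* Density synthesis is ``rho(x) = (1/V) * sum_hkl F(hkl) exp(-2 pi i h.x)``
  with ``x`` fractional, realized by scattering ``F`` into a complex
  frequency grid at indices ``(h mod N1, k mod N2, l mod N3)`` and applying
  ``numpy.fft.fftn`` (whose kernel is ``exp(-2 pi i k n / N)``), then
  dividing by ``V``.
* Phases are reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "UnitCell",
    "Atom",
    "FragmentStructure",
    "ReflectionSet",
    "VolumeGrid",
    "GridSpec",
    "PhaseErrorResult",
    "build_grid",
    "calc_structure_factors",
    "density_from_sf",
    "patterson_from_sf",
    "patterson_from_density",
    "sf_from_density",
    "normalize_map",
    "phase_error",
    "scattering_factor",
    "ELECTRON_COUNTS",
    "ATOMIC_MASSES",
]


class XtalError(ValueError):
    """Base class for crystallographic input errors."""


class InvalidCellError(XtalError):
    pass


class InvalidResolutionError(XtalError):
    pass


class EmptyStructureError(XtalError):
    pass


class NonRealDensityError(XtalError):
    pass


class InvalidMapError(XtalError):
    pass


class DomainMismatchError(XtalError):
    pass


# Electron counts (point-scatterer form factors) and standard atomic masses.
ELECTRON_COUNTS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# 4-term Cromer-Mann coefficients (International Tables vol. C, table 6.1.1.4)
# f(q) = sum_i a_i exp(-b_i q^2) + c  with  q = sin(theta)/lambda = 1/(2 d).
CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
}


@dataclass(frozen=True)
class UnitCell:
    """Orthorhombic unit cell; angles are fixed at 90 degrees."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InvalidCellError(f"cell edges must be positive, got {self.edges}")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def volume(self) -> float:
        return float(self.a * self.b * self.c)


@dataclass
class Atom:
    """A scatterer: element, Cartesian position (A), occupancy, B-factor (A^2)."""

    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.b_factor < 0:
            raise ValueError("B-factor must be non-negative")


@dataclass
class FragmentStructure:
    """A molecule in a box: atoms grouped into residues plus a unit cell.

    ``residues`` is an ordered list of ``(residue_type, (start, stop))``
    half-open index ranges that partition the atom list in chain order.
    """

    atoms: list[Atom]
    residues: list[tuple[str, tuple[int, int]]]
    cell: UnitCell

    def __post_init__(self) -> None:
        stops = 0
        for _, (start, stop) in self.residues:
            if start != stops or stop < start:
                raise ValueError("residue index ranges must partition the atom list")
            stops = stop
        if self.residues and stops != len(self.atoms):
            raise ValueError("residue index ranges must cover all atoms")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """Cartesian coordinates, shape (n_atoms, 3)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_positions(self, pos: np.ndarray, cell: UnitCell | None = None) -> "FragmentStructure":
        pos = np.asarray(pos, dtype=float)
        atoms = [replace(a, position=p.copy()) for a, p in zip(self.atoms, pos)]
        return FragmentStructure(atoms, list(self.residues), cell or self.cell)

    def wrapped(self) -> "FragmentStructure":
        """Wrap all atoms into [0,a) x [0,b) x [0,c)."""
        edges = self.cell.edges
        return self.with_positions(np.mod(self.positions, edges))

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[a.element] for a in self.atoms])

    def electron_count(self) -> float:
        return float(sum(ELECTRON_COUNTS[a.element] * a.occupancy for a in self.atoms))


def scattering_factor(element: str, s: np.ndarray, model: str = "point") -> np.ndarray:
    """Atomic form factor at scattering vector magnitude ``s = 1/d`` (1/A).

    ``point`` returns the element's electron count independent of angle
    (1 for unknown elements); ``gaussian`` evaluates the 4-term Cromer-Mann
    expansion for H, C, N, O, S.
    """
    s = np.asarray(s, dtype=float)
    if model == "point":
        return np.full_like(s, float(ELECTRON_COUNTS.get(element, 1)))
    if model == "gaussian":
        if element not in CROMER_MANN:
            raise ValueError(f"no gaussian form factor for element {element!r}")
        a, b, c = CROMER_MANN[element]
        q2 = (s / 2.0) ** 2
        f = np.full_like(s, c, dtype=float)
        for ai, bi in zip(a, b):
            f += ai * np.exp(-bi * q2)
        return f
    raise ValueError(f"unknown scattering model {model!r}")


@dataclass
class ReflectionSet:
    """Friedel-unique structure factors F(h,k,l) to a resolution limit.

    Stores one member of each Friedel pair plus F(0,0,0); the unique half
    is ``l > 0, or l == 0 and k > 0, or k == l == 0 and h >= 0``.
    """

    cell: UnitCell
    d_min: float
    hkl: np.ndarray  # (n, 3) int
    f: np.ndarray  # (n,) complex

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.f = np.asarray(self.f, dtype=complex)
        if self.hkl.shape != (len(self.f), 3):
            raise ValueError("hkl and f must have matching lengths")

    def __len__(self) -> int:
        return len(self.f)

    @property
    def d(self) -> np.ndarray:
        """Resolution of each reflection in A (inf for F(0,0,0))."""
        with np.errstate(divide="ignore"):
            inv_d2 = np.sum((self.hkl / self.cell.edges) ** 2, axis=1)
            return 1.0 / np.sqrt(inv_d2)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)

    @property
    def phases_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.f))

    def full_sphere(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to the full sphere using Friedel symmetry F(-h) = conj F(h)."""
        non_origin = np.any(self.hkl != 0, axis=1)
        hkl = np.concatenate([self.hkl, -self.hkl[non_origin]])
        f = np.concatenate([self.f, np.conj(self.f[non_origin])])
        return hkl, f

    def sort_key(self) -> np.ndarray:
        return np.lexsort((self.hkl[:, 2], self.hkl[:, 1], self.hkl[:, 0]))


def friedel_unique_hkl(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller indices in the Friedel-unique half with d >= d_min, plus (0,0,0)."""
    if d_min <= 0:
        raise InvalidResolutionError("d_min must be positive")
    edges = cell.edges
    hmax = np.floor(edges / d_min).astype(int)
    h, k, l = np.meshgrid(
        np.arange(-hmax[0], hmax[0] + 1),
        np.arange(-hmax[1], hmax[1] + 1),
        np.arange(-hmax[2], hmax[2] + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    inv_d2 = np.sum((hkl / edges) ** 2, axis=1)
    in_sphere = inv_d2 <= 1.0 / d_min**2 + 1e-12
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    unique_half = (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h >= 0))
    return hkl[in_sphere & unique_half]


def calc_structure_factors(
    structure: FragmentStructure,
    d_min: float,
    scattering_model: str = "point",
    include_hydrogens: bool = True,
) -> ReflectionSet:
    """Structure factors by direct summation over atoms.

    F(hkl) = sum_j f_j(s) occ_j exp(-B_j s^2 / 4) exp(2 pi i (h x_j/a + k y_j/b + l z_j/c))
    with s = 1/d, over the Friedel-unique half sphere to ``d_min`` plus F(0,0,0).
    """
    atoms = structure.atoms
    if not include_hydrogens:
        atoms = [a for a in atoms if a.element != "H"]
    if not atoms:
        raise EmptyStructureError("structure has no atoms")
    hkl = friedel_unique_hkl(structure.cell, d_min)
    edges = structure.cell.edges
    inv_d2 = np.sum((hkl / edges) ** 2, axis=1)
    s = np.sqrt(inv_d2)

    frac = np.array([a.position for a in atoms]) / edges  # (m, 3)
    phases = 2.0 * np.pi * (hkl @ frac.T)  # (n, m)
    f_tot = np.zeros(len(hkl), dtype=complex)
    for j, atom in enumerate(atoms):
        fj = scattering_factor(atom.element, s, scattering_model)
        fj = fj * atom.occupancy * np.exp(-atom.b_factor * inv_d2 / 4.0)
        f_tot += fj * np.exp(1j * phases[:, j])
    return ReflectionSet(structure.cell, d_min, hkl, f_tot)


@dataclass(frozen=True)
class GridSpec:
    """Grid dimensions plus nominal voxel spacing (A per voxel)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]


@dataclass
class VolumeGrid:
    """A real-valued 3D grid sampling one unit cell.

    ``kind`` is one of density | patterson | prediction | partial; the voxel
    at index (i,j,k) samples fractional position (i/N1, j/N2, k/N3).
    ``spacing`` records the nominal (requested) sampling interval; the exact
    interval along axis i is ``cell edge / dims[i]``.
    """

    values: np.ndarray
    cell: UnitCell
    spacing: tuple[float, float, float]
    kind: str = "density"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be 3-dimensional")
        if self.kind not in ("density", "patterson", "prediction", "partial"):
            raise ValueError(f"unknown grid kind {self.kind!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy_with(self, values: np.ndarray, kind: str | None = None,
                  normalized: bool | None = None) -> "VolumeGrid":
        return VolumeGrid(
            values, self.cell, self.spacing,
            kind if kind is not None else self.kind,
            self.normalized if normalized is None else normalized,
        )


def build_grid(cell: UnitCell, d_min: float, oversampling: float = 3.0) -> GridSpec:
    """Grid dimensions for sampling a cell at resolution ``d_min``.

    The voxel spacing is ``d_min / oversampling`` on every axis, and each
    dimension is the smallest even integer whose extent covers the cell edge.
    """
    if d_min <= 0:
        raise InvalidResolutionError("d_min must be positive")
    if oversampling < 2:
        raise ValueError("oversampling must be >= 2 to avoid aliasing")
    spacing = d_min / oversampling
    dims = []
    for edge in cell.edges:
        n = math.ceil(edge / spacing - 1e-9)
        if n % 2:
            n += 1
        dims.append(max(n, 2))
    return GridSpec(tuple(dims), (spacing,) * 3)


def _frequency_grid(refs: ReflectionSet, dims: tuple[int, int, int],
                    values: np.ndarray) -> np.ndarray:
    """Scatter per-reflection complex values onto a full-sphere frequency grid."""
    hkl, _ = refs.full_sphere()
    non_origin = np.any(refs.hkl != 0, axis=1)
    vals = np.concatenate([values, np.conj(values[non_origin])])
    grid = np.zeros(dims, dtype=complex)
    idx = np.mod(hkl, np.array(dims))
    np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), vals)
    return grid


def _synthesize(refs: ReflectionSet, dims: tuple[int, int, int],
                coeffs: np.ndarray, kind: str,
                spacing: tuple[float, float, float]) -> VolumeGrid:
    grid = _frequency_grid(refs, dims, coeffs)
    rho = np.fft.fftn(grid) / refs.cell.volume
    scale = np.max(np.abs(rho.real))
    if scale > 0 and np.max(np.abs(rho.imag)) > 1e-6 * scale:
        raise NonRealDensityError(
            "Fourier synthesis is not real: input violates Friedel symmetry"
        )
    return VolumeGrid(rho.real, refs.cell, spacing, kind=kind)


def _grid_spec_for(refs: ReflectionSet, grid: GridSpec | None) -> GridSpec:
    if grid is not None:
        return grid
    return build_grid(refs.cell, refs.d_min, 3.0)


def density_from_sf(refs: ReflectionSet, grid: GridSpec | None = None) -> VolumeGrid:
    """Electron-density synthesis: rho = (1/V) sum F(hkl) exp(-2 pi i h.x)."""
    spec = _grid_spec_for(refs, grid)
    return _synthesize(refs, spec.dims, refs.f, "density", spec.spacing)


def patterson_from_sf(refs: ReflectionSet, grid: GridSpec | None = None) -> VolumeGrid:
    """Patterson synthesis: amplitudes squared, phases zeroed."""
    spec = _grid_spec_for(refs, grid)
    coeffs = (refs.amplitudes ** 2).astype(complex)
    return _synthesize(refs, spec.dims, coeffs, "patterson", spec.spacing)


def sf_from_density(e: VolumeGrid, d_min: float) -> ReflectionSet:
    """Recover structure factors from a sampled map (inverse of density_from_sf).

    Band-limited to ``d_min``; exact for maps synthesized on the same grid.
    """
    f_grid = np.fft.ifftn(e.values) * e.cell.volume
    hkl = friedel_unique_hkl(e.cell, d_min)
    idx = np.mod(hkl, np.array(e.dims))
    return ReflectionSet(e.cell, d_min, hkl, f_grid[idx[:, 0], idx[:, 1], idx[:, 2]])


def patterson_from_density(e: VolumeGrid) -> VolumeGrid:
    """Patterson map as the periodic autocorrelation of the density.

    In frequency space the inverse-shifted copy of ``e`` becomes the complex
    conjugate, so p = Re(F^-1... realized here as
    p = (1/V) * FFT(|V * IFFT(e)|^2), matching the squared-amplitude route.
    """
    f_grid = np.fft.ifftn(e.values) * e.cell.volume
    p = np.fft.fftn(np.abs(f_grid) ** 2) / e.cell.volume
    return VolumeGrid(p.real, e.cell, e.spacing, kind="patterson")


def normalize_map(m: VolumeGrid) -> VolumeGrid:
    """Scale values into [-1, 1] by dividing by max |value|.

    The zero level (and hence the sign pattern) is preserved; an all-zero map
    is returned unchanged. Idempotent.
    """
    if not np.all(np.isfinite(m.values)):
        raise InvalidMapError("map contains NaN or Inf values")
    peak = np.max(np.abs(m.values))
    values = m.values if peak == 0 else m.values / peak
    return m.copy_with(values, normalized=True)


@dataclass
class PhaseErrorResult:
    """Mean absolute phase difference, overall and in resolution shells.

    Shells are equal-count bins ordered from low resolution (large d) to
    high; ``shell_frac_below_60`` is the fraction of reflections in each
    shell with error < 60 deg.
    """

    mean_deg: float
    weighted_mean_deg: float
    shell_d_max: np.ndarray
    shell_d_min: np.ndarray
    shell_mean_deg: np.ndarray
    shell_frac_below_60: np.ndarray
    shell_count: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.shell_mean_deg)


def wrap_phase_diff_deg(delta: np.ndarray) -> np.ndarray:
    """Absolute phase difference wrapped into [0, 180] degrees."""
    return np.abs((np.asarray(delta) + 180.0) % 360.0 - 180.0)


def phase_error(pred: ReflectionSet, truth: ReflectionSet, n_shells: int = 10) -> PhaseErrorResult:
    """Compare phases of two reflection sets sharing an (h,k,l) domain.

    F(0,0,0) is excluded. The overall value is the unweighted mean of the
    wrapped absolute differences; an amplitude-weighted mean (weights from
    the truth amplitudes) is reported alongside.
    """
    ka, kb = pred.sort_key(), truth.sort_key()
    if pred.hkl.shape != truth.hkl.shape or not np.array_equal(pred.hkl[ka], truth.hkl[kb]):
        raise DomainMismatchError("reflection sets cover different (h,k,l) domains")
    if (pred.cell.a, pred.cell.b, pred.cell.c) != (truth.cell.a, truth.cell.b, truth.cell.c):
        raise DomainMismatchError("reflection sets have different unit cells")
    hkl = pred.hkl[ka]
    non_origin = np.any(hkl != 0, axis=1)
    dphi = wrap_phase_diff_deg(pred.phases_deg[ka] - truth.phases_deg[kb])[non_origin]
    d = truth.d[kb][non_origin]
    w = truth.amplitudes[kb][non_origin]

    mean = float(np.mean(dphi))
    wmean = float(np.sum(w * dphi) / np.sum(w)) if np.sum(w) > 0 else mean

    order = np.argsort(-d, kind="stable")  # low resolution (large d) first
    shells = np.array_split(order, n_shells)
    smax, smin, smean, sfrac, scount = [], [], [], [], []
    for sh in shells:
        if len(sh) == 0:
            smax.append(np.nan); smin.append(np.nan)
            smean.append(np.nan); sfrac.append(np.nan); scount.append(0)
            continue
        smax.append(float(d[sh].max()))
        smin.append(float(d[sh].min()))
        smean.append(float(np.mean(dphi[sh])))
        sfrac.append(float(np.mean(dphi[sh] < 60.0)))
        scount.append(len(sh))
    return PhaseErrorResult(
        mean, wmean,
        np.array(smax), np.array(smin), np.array(smean),
        np.array(sfrac), np.array(scount),
    )
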