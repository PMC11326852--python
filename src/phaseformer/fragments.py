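"""Random peptide-like fragment generation.

Chains of idealized residues joined by peptide bonds with standard bond
lengths/angles and random backbone dihedrals. Geometry realism is
deliberately minimal — enough that fragments look like short peptides
(correct connectivity, no steric overlaps), which is what the density /
Patterson pipeline and the model need; it makes no claim of Ramachandran
statistics or rotamer diversity.

Backbone placement uses internal coordinates (the natural-extension
reference frame): each new atom is placed from the three preceding ones by
bond length, bond angle and dihedral. Side-chain and carbonyl atoms are
copied from the residue template after superimposing its N/CA/C triad onto
the freshly placed backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import residues as _res
from .dataset import BuilderConfig, DiscardedExample, ExampleRecord, bin_and_filter, build_example
from .xtal import Atom, FragmentStructure, UnitCell

__all__ = ["GeneratorConfig", "generate_fragment", "generate_dataset", "GenerationFailedError"]

# Idealized backbone geometry (A, degrees)
BOND_C_N = 1.33
BOND_N_CA = 1.46
BOND_CA_C = 1.52
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 110.4
OMEGA = 180.0  # trans peptide
CLASH_DISTANCE = 1.8  # A, minimum allowed non-bonded intramolecular distance


class GenerationFailedError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """Settings for random fragment generation.

    ``dihedral_distribution``: "uniform" draws phi/psi uniformly on
    (-180, 180]; "helix-biased" draws near alpha-helical values
    (phi ~ N(-63, 8), psi ~ N(-42, 8)), which keeps long chains compact
    and nearly clash-free.
    """

    n_residues: int = 2
    residue_alphabet: tuple[str, ...] = _res.STANDARD_RESIDUES
    seed: int = 0
    dihedral_distribution: str = "uniform"
    include_hydrogens: bool = False
    max_tries: int = 500

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if not self.residue_alphabet:
            raise ValueError("residue alphabet must be non-empty")
        if self.dihedral_distribution not in ("uniform", "helix-biased"):
            raise ValueError(
                f"unknown dihedral distribution {self.dihedral_distribution!r}")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a new atom D given chain A-B-C, |CD|, angle(BCD), dihedral(ABCD)."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        -np.sin(angle) * np.cos(dihedral),
        -np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t with R @ src_i + t ~= dst_i (least squares)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, dc - r @ sc


def _draw_dihedrals(rng: np.random.Generator, n: int, kind: str):
    if kind == "uniform":
        phi = rng.uniform(-180.0, 180.0, size=n)
        psi = rng.uniform(-180.0, 180.0, size=n)
    else:
        phi = rng.normal(-63.0, 8.0, size=n)
        psi = rng.normal(-42.0, 8.0, size=n)
    return phi, psi


def _build_chain(seq: list[str], phi: np.ndarray, psi: np.ndarray,
                 include_hydrogens: bool):
    """Place one chain; returns (atoms, residues) in FragmentStructure layout."""
    atoms: list[Atom] = []
    residues: list[tuple[str, tuple[int, int]]] = []
    prev_n = prev_ca = prev_c = None
    for i, res_type in enumerate(seq):
        names, elements, tcoords = _res.get_template(res_type, include_hydrogens)
        i_n, i_ca, i_c = _res.backbone_indices(names)
        if i == 0:
            n_pos = np.zeros(3)
            ca_pos = np.array([BOND_N_CA, 0.0, 0.0])
            ang = np.radians(ANGLE_N_CA_C)
            c_pos = ca_pos + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_pos = _place_atom(prev_n, prev_ca, prev_c,
                                BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
            ca_pos = _place_atom(prev_ca, prev_c, n_pos,
                                 BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_pos = _place_atom(prev_c, n_pos, ca_pos,
                                BOND_CA_C, ANGLE_N_CA_C, phi[i])
        r, t = _kabsch(tcoords[[i_n, i_ca, i_c]], np.stack([n_pos, ca_pos, c_pos]))
        placed = tcoords @ r.T + t
        placed[i_n], placed[i_ca], placed[i_c] = n_pos, ca_pos, c_pos
        start = len(atoms)
        for el, xyz in zip(elements, placed):
            atoms.append(Atom(el, xyz))
        residues.append((res_type, (start, start + len(elements))))
        prev_n, prev_ca, prev_c = n_pos, ca_pos, c_pos
    return atoms, residues


def _has_clash(atoms: list[Atom],
               residues: list[tuple[str, tuple[int, int]]],
               names_per_res: list[list[str]]) -> bool:
    """Any non-bonded pair (different residues, not the peptide C-N link) < 1.8 A."""
    pos = np.array([a.position for a in atoms])
    res_of = np.empty(len(atoms), dtype=int)
    for ri, (_, (s, e)) in enumerate(residues):
        res_of[s:e] = ri
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    close = d2 < CLASH_DISTANCE**2
    np.fill_diagonal(close, False)
    ii, jj = np.nonzero(close)
    for i, j in zip(ii, jj):
        ri, rj = res_of[i], res_of[j]
        if ri == rj:
            continue
        if abs(ri - rj) == 1:
            lo, hi = (i, j) if ri < rj else (j, i)
            name_lo = names_per_res[res_of[lo]][lo - residues[res_of[lo]][1][0]]
            name_hi = names_per_res[res_of[hi]][hi - residues[res_of[hi]][1][0]]
            if name_lo == "C" and name_hi == "N":
                continue
        return True
    return False


def generate_fragment(config: GeneratorConfig) -> FragmentStructure:
    """Generate one random fragment; deterministic in ``config.seed``.

    Chains are rejection-resampled until no non-bonded intramolecular pair
    is closer than 1.8 A; raises GenerationFailedError when the budget
    (``config.max_tries``) is exhausted.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(config.max_tries):
        seq = [str(s) for s in rng.choice(config.residue_alphabet,
                                          size=config.n_residues)]
        phi, psi = _draw_dihedrals(rng, config.n_residues,
                                   config.dihedral_distribution)
        atoms, residues = _build_chain(seq, phi, psi, config.include_hydrogens)
        names_per_res = [
            _res.get_template(rt, config.include_hydrogens)[0] for rt in seq
        ]
        if not _has_clash(atoms, residues, names_per_res):
            pos = np.array([a.position for a in atoms])
            span = pos.max(axis=0) - pos.min(axis=0)
            cell = UnitCell(*np.maximum(span, 1.0))
            frag = FragmentStructure(atoms, residues, cell)
            return frag.with_positions(pos - pos.min(axis=0))
    raise GenerationFailedError(
        f"no clash-free chain in {config.max_tries} tries (seed {config.seed})")


@dataclass
class DatasetResult:
    """Examples that survived the builder, grouped by grid dims, plus manifest."""

    bins: dict[tuple[int, int, int], list[ExampleRecord]]
    manifest: dict = field(default_factory=dict)

    @property
    def examples(self) -> list[ExampleRecord]:
        return [ex for exs in self.bins.values() for ex in exs]


class EmptyDatasetError(RuntimeError):
    pass


def generate_dataset(n: int, gen_config: GeneratorConfig,
                     builder_config: BuilderConfig) -> DatasetResult:
    """Generate ``n`` fragments, build examples, bin and filter.

    Fragment i uses seed ``gen_config.seed + i``; the manifest records every
    per-fragment seed and each discard reason. Raises EmptyDatasetError if
    nothing survives.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    survivors: list[ExampleRecord] = []
    discards: dict[str, str] = {}
    seeds = {}
    for i in range(n):
        seed = gen_config.seed + i
        cfg_i = GeneratorConfig(
            n_residues=gen_config.n_residues,
            residue_alphabet=gen_config.residue_alphabet,
            seed=seed,
            dihedral_distribution=gen_config.dihedral_distribution,
            include_hydrogens=gen_config.include_hydrogens,
            max_tries=gen_config.max_tries,
        )
        ex_id = f"frag-{i:05d}"
        seeds[ex_id] = seed
        try:
            frag = generate_fragment(cfg_i)
            survivors.append(build_example(frag, builder_config, example_id=ex_id))
        except (DiscardedExample, GenerationFailedError) as exc:
            discards[ex_id] = getattr(exc, "reason", "generation_failed")
    bins, report = bin_and_filter(survivors, builder_config.min_batch)
    if not bins:
        raise EmptyDatasetError("no examples survived generation and filtering")
    manifest = {
        "n_requested": n,
        "seeds": seeds,
        "discards": discards,
        "bin_filter": report,
        "generator": {
            "n_residues": gen_config.n_residues,
            "residue_alphabet": list(gen_config.residue_alphabet),
            "seed": gen_config.seed,
            "dihedral_distribution": gen_config.dihedral_distribution,
        },
    }
    return DatasetResult(bins, manifest)
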