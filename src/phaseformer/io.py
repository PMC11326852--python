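"""File I/O: PDB coordinates, CCP4/MRC maps, reflection lists, datasets,
and model checkpoints.

PDB and CCP4 handling goes through gemmi; datasets are stored as one
compressed .npz per grid-size bin plus a JSON manifest; checkpoints are a
single .npz bundling the config (as JSON) with the named parameter arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np

from .dataset import ExampleRecord, PartialStructureSet
from .nn.model import ModelConfig, ModelParameters, init_parameters
from .xtal import Atom, FragmentStructure, ReflectionSet, UnitCell, VolumeGrid

__all__ = [
    "read_pdb", "write_pdb", "read_ccp4", "write_ccp4",
    "read_reflections_text", "write_reflections_text",
    "save_dataset", "load_dataset", "save_checkpoint", "load_checkpoint",
]


def read_pdb(path) -> FragmentStructure:
    """Read ATOM/HETATM records into a FragmentStructure.

    Residues are taken in file order (1-based numbering preserved in the
    residue names is not needed downstream); occupancy and B-factor
    columns are kept. The cell comes from CRYST1 when present, else from
    the coordinate bounding box.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[Atom] = []
    residues: list[tuple[str, tuple[int, int]]] = []
    for model in st:
        for chain in model:
            for res in chain:
                start = len(atoms)
                for at in res:
                    atoms.append(Atom(
                        at.element.name,
                        np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ) if at.occ > 0 else 1.0,
                        b_factor=float(at.b_iso),
                    ))
                residues.append((res.name, (start, len(atoms))))
        break  # first model only
    if not atoms:
        raise ValueError(f"no atoms in {path}")
    if st.cell.a > 1 and st.cell.b > 1 and st.cell.c > 1:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c)
    else:
        pos = np.array([a.position for a in atoms])
        span = np.maximum(pos.max(axis=0) - pos.min(axis=0), 1.0)
        cell = UnitCell(*span)
    return FragmentStructure(atoms, residues, cell)


def write_pdb(structure: FragmentStructure, path) -> None:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(structure.cell.a, structure.cell.b,
                             structure.cell.c, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    counts: dict[str, int] = {}
    for i, (res_type, (start, stop)) in enumerate(structure.residues, start=1):
        res = gemmi.Residue()
        res.name = res_type
        res.seqid = gemmi.SeqId(i, " ")
        counts.clear()  # atom names are element+counter within each residue
        for atom in structure.atoms[start:stop]:
            a = gemmi.Atom()
            el = atom.element
            counts[el] = counts.get(el, 0) + 1
            a.name = f"{el}{counts[el]}"
            a.element = gemmi.Element(el)
            a.pos = gemmi.Position(*atom.position)
            a.occ = atom.occupancy
            a.b_iso = atom.b_factor
            res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def write_ccp4(grid: VolumeGrid, path) -> None:
    """Write a VolumeGrid as a CCP4/MRC map (mode 2, float32), P1."""
    g = gemmi.FloatGrid(np.asarray(grid.values, dtype=np.float32),
                        gemmi.UnitCell(grid.cell.a, grid.cell.b, grid.cell.c,
                                       90, 90, 90),
                        gemmi.SpaceGroup("P1"))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_ccp4(path, kind: str = "density") -> VolumeGrid:
    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, dtype=float)
    cell = UnitCell(m.grid.unit_cell.a, m.grid.unit_cell.b, m.grid.unit_cell.c)
    spacing = tuple(e / n for e, n in zip(cell.edges, values.shape))
    return VolumeGrid(values, cell, spacing, kind=kind)


def write_reflections_text(refs: ReflectionSet, path) -> None:
    """Plain-text reflection list: 'h k l |F| phi_deg' per line."""
    with open(path, "w") as fh:
        fh.write(f"# cell {refs.cell.a:.6f} {refs.cell.b:.6f} {refs.cell.c:.6f} "
                 f"d_min {refs.d_min:.6f}\n")
        for (h, k, l), amp, phi in zip(refs.hkl, refs.amplitudes, refs.phases_deg):
            fh.write(f"{h:5d} {k:5d} {l:5d} {amp:16.8e} {phi:12.6f}\n")


def read_reflections_text(path) -> ReflectionSet:
    with open(path) as fh:
        header = fh.readline().split()
        cell = UnitCell(float(header[2]), float(header[3]), float(header[4]))
        d_min = float(header[6])
        hkl, f = [], []
        for line in fh:
            parts = line.split()
            if len(parts) != 5:
                continue
            hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
            amp, phi = float(parts[3]), np.radians(float(parts[4]))
            f.append(amp * np.exp(1j * phi))
    return ReflectionSet(cell, d_min, np.array(hkl, dtype=int), np.array(f))


def _grid_to_meta(g: VolumeGrid) -> dict:
    return {"spacing": list(g.spacing), "kind": g.kind, "normalized": g.normalized}


def save_dataset(bins: dict, manifest: dict, outdir) -> None:
    """Serialize binned examples: one npz per dims bin + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bin_entries = []
    for bi, dims in enumerate(sorted(bins.keys())):
        exs: list[ExampleRecord] = bins[dims]
        fname = f"bin-{'x'.join(map(str, dims))}.npz"
        arrays = {
            "patterson": np.stack([ex.patterson.values for ex in exs]).astype(np.float32),
            "density": np.stack([ex.density.values for ex in exs]).astype(np.float32),
        }
        j = len(exs[0].partials)
        if j > 0:
            arrays["partials"] = np.stack(
                [ex.partials.as_array() for ex in exs]).astype(np.float32)
        np.savez_compressed(outdir / fname, **arrays)
        bin_entries.append({
            "file": fname,
            "dims": list(dims),
            "examples": [
                {
                    "id": ex.id,
                    "cell": [ex.cell.a, ex.cell.b, ex.cell.c],
                    "n_residues": ex.n_residues,
                    "residue_types": ex.residue_types,
                    "meta": ex.meta,
                    "patterson": _grid_to_meta(ex.patterson),
                    "density": _grid_to_meta(ex.density),
                }
                for ex in exs
            ],
        })
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"bins": bin_entries, **manifest}, fh, indent=1, sort_keys=True)


def load_dataset(indir) -> tuple[dict, dict]:
    """Inverse of save_dataset; returns (bins, manifest)."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    bins: dict = {}
    for entry in manifest["bins"]:
        data = np.load(indir / entry["file"])
        dims = tuple(entry["dims"])
        exs = []
        for i, em in enumerate(entry["examples"]):
            cell = UnitCell(*em["cell"])
            pm, dm = em["patterson"], em["density"]
            patterson = VolumeGrid(data["patterson"][i].astype(float), cell,
                                   tuple(pm["spacing"]), pm["kind"], pm["normalized"])
            density = VolumeGrid(data["density"][i].astype(float), cell,
                                 tuple(dm["spacing"]), dm["kind"], dm["normalized"])
            if "partials" in data:
                partials = PartialStructureSet([
                    VolumeGrid(data["partials"][i, jj].astype(float), cell,
                               tuple(pm["spacing"]), "partial", True)
                    for jj in range(data["partials"].shape[1])
                ])
            else:
                partials = PartialStructureSet([])
            exs.append(ExampleRecord(
                id=em["id"], patterson=patterson, density=density,
                partials=partials, cell=cell, n_residues=em["n_residues"],
                residue_types=em["residue_types"], meta=em["meta"]))
        bins[dims] = exs
    return bins, manifest


def save_checkpoint(params: ModelParameters, path, history: list | None = None) -> None:
    """Single-file checkpoint: config JSON + named float64 arrays."""
    payload = {f"param/{k}": v for k, v in params.state_arrays().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps(params.config.to_dict()).encode(), dtype=np.uint8)
    if history is not None:
        payload["history_json"] = np.frombuffer(
            json.dumps(history).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> tuple[ModelParameters, list]:
    data = np.load(path)
    config = ModelConfig.from_dict(
        json.loads(bytes(data["config_json"]).decode()))
    params = init_parameters(config)
    params.load_arrays({k[len("param/"):]: data[k] for k in data.files
                        if k.startswith("param/")})
    history = (json.loads(bytes(data["history_json"]).decode())
               if "history_json" in data.files else [])
    return params, history
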