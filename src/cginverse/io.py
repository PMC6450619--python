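"""File I/O: coordinates (GRO/XYZ via MDAnalysis), schemes, topologies,
distribution sets (text and HDF5) and run manifests.

Internal length unit is nm throughout; MDAnalysis works in Å, so every
coordinate crossing that boundary is converted.  XYZ files carry no box,
so trajectories written as XYZ get a JSON box sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .distributions import Distribution, DistributionSet
from .mapping import (
    AtomisticTopology,
    Bead,
    BondedTerms,
    CGTopology,
    MappingScheme,
)

__all__ = [
    "read_coordinates",
    "write_xyz_trajectory",
    "load_mapping_scheme",
    "save_mapping_scheme",
    "load_atomistic_topology",
    "save_atomistic_topology",
    "load_cg_topology",
    "save_cg_topology",
    "save_distribution_set",
    "load_distribution_set",
    "save_distribution_set_h5",
    "load_distribution_set_h5",
    "write_manifest",
]

_A = 10.0  # Å per nm


def read_coordinates(path: str | Path, box: list[float] | None = None):
    """Read a (multi-frame) GRO/XYZ file -> (frames nm, boxes nm, names).

    XYZ files carry no box: pass one explicitly or place a ``<file>.box.json``
    sidecar next to the file.
    """
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe(str(path))
    frames, boxes = [], []
    sidecar = path.with_suffix(path.suffix + ".box.json")
    if box is None and sidecar.exists():
        box = json.loads(sidecar.read_text())["box_nm"]
    for ts in u.trajectory:
        frames.append(ts.positions / _A)
        if ts.dimensions is not None and ts.dimensions[:3].any():
            boxes.append(ts.dimensions[:3] / _A)
        elif box is not None:
            boxes.append(np.asarray(box, dtype=float))
        else:
            raise ValueError(f"{path}: no box in file and none provided")
    names = [a.name for a in u.atoms]
    return np.array(frames), np.array(boxes), names


def write_xyz_trajectory(path: str | Path, frames: np.ndarray, box: np.ndarray,
                         names: list[str] | None = None) -> None:
    """Write frames (nm) as multi-frame XYZ (Å) with a box sidecar."""
    path = Path(path)
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    names = names or [f"B{i}" for i in range(n)]
    with open(path, "w") as fh:
        for f in range(frames.shape[0]):
            fh.write(f"{n}\nframe {f}\n")
            for name, (x, y, z) in zip(names, frames[f] * _A):
                fh.write(f"{name[:8]:8s} {x:.6f} {y:.6f} {z:.6f}\n")
    sidecar = path.with_suffix(path.suffix + ".box.json")
    sidecar.write_text(json.dumps({"box_nm": list(np.asarray(box, float))}))


# ---------------------------------------------------------------------------
# mapping schemes and topologies (YAML)


def save_mapping_scheme(scheme: MappingScheme, path: str | Path) -> None:
    data = {
        "species": scheme.species,
        "types": list(scheme.type_alphabet),
        "beads": [{"name": b.name, "type": b.type, "atoms": list(b.atoms)}
                  for b in scheme.beads],
    }
    if scheme.cg_bonds is not None:
        data["cg_bonds"] = [[int(i), int(j)] for i, j in scheme.cg_bonds]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_mapping_scheme(path: str | Path,
                        topo: AtomisticTopology | None = None) -> MappingScheme:
    """Load a scheme; atom entries may be indices or (unique) atom names."""
    data = yaml.safe_load(Path(path).read_text())
    beads = []
    for b in data["beads"]:
        atoms = []
        for a in b["atoms"]:
            if isinstance(a, int):
                atoms.append(a)
            else:
                if topo is None:
                    raise ValueError("atom names in scheme require a topology")
                atoms.append(topo.names.index(a))
        beads.append(Bead(b["name"], b["type"], tuple(atoms)))
    cg_bonds = data.get("cg_bonds")
    if cg_bonds is not None:
        cg_bonds = [tuple(b) for b in cg_bonds]
    return MappingScheme(data["species"], beads, tuple(data.get("types", ())),
                         cg_bonds=cg_bonds)


def save_atomistic_topology(topo: AtomisticTopology, path: str | Path) -> None:
    data = {
        "species": topo.species,
        "names": list(topo.names),
        "masses": [float(m) for m in topo.masses],
        "charges": [float(q) for q in topo.charges],
        "bonds": [[int(i), int(j)] for i, j in topo.bonds],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_atomistic_topology(path: str | Path) -> AtomisticTopology:
    d = yaml.safe_load(Path(path).read_text())
    return AtomisticTopology(d["names"], np.array(d["masses"]),
                             np.array(d["charges"]),
                             [tuple(b) for b in d["bonds"]], d["species"])


def save_cg_topology(top: CGTopology, path: str | Path) -> None:
    data = {
        "bead_types": list(top.bead_types),
        "bead_names": list(top.bead_names),
        "masses": [float(m) for m in top.masses],
        "charges": [float(q) for q in top.charges],
        "molecule_ids": [int(m) for m in top.molecule_ids],
        "bonds": [{"idx": list(map(int, i)), "type": t} for i, t in top.terms.bonds],
        "angles": [{"idx": list(map(int, i)), "type": t} for i, t in top.terms.angles],
        "torsions": [{"idx": list(map(int, i)), "type": t} for i, t in top.terms.torsions],
        "exclusions": [list(map(int, p)) for p in sorted(top.exclusions)],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_cg_topology(path: str | Path) -> CGTopology:
    d = yaml.safe_load(Path(path).read_text())
    terms = BondedTerms(
        bonds=[(tuple(t["idx"]), t["type"]) for t in d["bonds"]],
        angles=[(tuple(t["idx"]), t["type"]) for t in d["angles"]],
        torsions=[(tuple(t["idx"]), t["type"]) for t in d["torsions"]],
    )
    return CGTopology(
        bead_types=d["bead_types"],
        masses=np.array(d["masses"]),
        charges=np.array(d["charges"]),
        terms=terms,
        exclusions={tuple(p) for p in d["exclusions"]},
        molecule_ids=np.array(d["molecule_ids"]),
        bead_names=d.get("bead_names", []),
    )


# ---------------------------------------------------------------------------
# distribution sets


def save_distribution_set(ds: DistributionSet, outdir: str | Path) -> None:
    """Two-column-plus text files (centre, density/g, mean count) per member."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for d in ds:
        safe = d.name.replace("/", "_")
        with open(outdir / f"{d.kind}_{safe}.dist", "w") as fh:
            fh.write(f"# kind: {d.kind}\n# name: {d.name}\n")
            fh.write(f"# bin_width: {d.bin_width:.17g}\n")
            fh.write(f"# edge0: {d.edges[0]:.17g}\n")
            fh.write(f"# n_samples: {d.n_samples}\n# n_frames: {d.n_frames}\n")
            cm = d.counts_mean if d.counts_mean is not None else np.zeros(d.n_bins)
            for x, v, c in zip(d.centers, d.values, cm):
                fh.write(f"{x:.17g} {v:.17g} {c:.17g}\n")


def load_distribution_set(outdir: str | Path) -> DistributionSet:
    members = []
    for p in sorted(Path(outdir).glob("*.dist")):
        meta, rows = {}, []
        for line in p.read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
            elif line:
                rows.append([float(x) for x in line.split()])
        arr = np.array(rows)
        w = float(meta["bin_width"])
        e0 = float(meta["edge0"])
        edges = e0 + w * np.arange(len(arr) + 1)
        members.append(Distribution(
            kind=meta["kind"], name=meta["name"], edges=edges, values=arr[:, 1],
            counts_mean=arr[:, 2], n_samples=int(meta.get("n_samples", 0)),
            n_frames=int(meta.get("n_frames", 0)),
        ))
    return DistributionSet(members)


def save_distribution_set_h5(ds: DistributionSet, path: str | Path) -> None:
    """HDF5 container including per-frame count matrices where present."""
    with h5py.File(path, "w") as h5:
        for i, d in enumerate(ds):
            g = h5.create_group(f"dist_{i:03d}")
            g.attrs["kind"] = d.kind
            g.attrs["name"] = d.name
            g.attrs["n_samples"] = d.n_samples
            g.attrs["n_frames"] = d.n_frames
            g.create_dataset("edges", data=d.edges)
            g.create_dataset("values", data=d.values)
            if d.counts_mean is not None:
                g.create_dataset("counts_mean", data=d.counts_mean)
            if d.frames is not None:
                g.create_dataset("frames", data=d.frames, compression="gzip")


def load_distribution_set_h5(path: str | Path) -> DistributionSet:
    members = []
    with h5py.File(path, "r") as h5:
        for key in sorted(h5.keys()):
            g = h5[key]
            members.append(Distribution(
                kind=g.attrs["kind"], name=g.attrs["name"],
                edges=g["edges"][()], values=g["values"][()],
                counts_mean=g["counts_mean"][()] if "counts_mean" in g else None,
                n_samples=int(g.attrs["n_samples"]),
                n_frames=int(g.attrs["n_frames"]),
                frames=g["frames"][()] if "frames" in g else None,
            ))
    return DistributionSet(members)


def write_manifest(outdir: str | Path, command: str, params: dict,
                   seed: int | None = None,
                   inputs: list[str | Path] = ()) -> Path:
    """Provenance record: command, parameters, seed, input hashes, versions."""
    import cginverse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command": command,
        "params": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in params.items()},
        "seed": seed,
        "input_sha256": hashes,
        "versions": {"cginverse": cginverse.__version__, "numpy": np.__version__},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
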