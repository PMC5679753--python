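"""Serialization: VTK legacy PolyData and OFF meshes, configs, manifests.

Trajectory snapshots are written as inspectable text: the membrane as
triangle cells (VTK legacy ASCII PolyData, or OFF), proteins as a point set
tagged with protein id and sphere index (VTK vertices + CSV).  Round-trips
preserve connectivity exactly and positions to better than 1e-9.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .energy import EnergyParams
from .engine import MCParams
from .mesh import TriMesh

FORMATS = ("vtk", "off")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh_vtk(mesh: TriMesh, path) -> None:
    p = Path(path)
    V, F = mesh.n_vertices, mesh.n_triangles
    lines = [
        "# vtk DataFile Version 3.0",
        f"membrane tube; box_length={mesh.box_length!r} "
        f"nominal_radius={mesh.nominal_radius!r}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {V} double",
    ]
    for x, y, z in mesh.positions:
        lines.append(f"{x:.17g} {y:.17g} {z:.17g}")
    lines.append(f"POLYGONS {F} {4 * F}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"FIELD FieldData 2")
    lines.append("box_length 1 1 double")
    lines.append(f"{mesh.box_length:.17g}")
    lines.append("nominal_radius 1 1 double")
    lines.append(f"{mesh.nominal_radius:.17g}")
    p.write_text("\n".join(lines) + "\n")


def read_mesh_vtk(path) -> TriMesh:
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    pos = tris = None
    box_length = nominal_radius = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            n = int(parts[1])
            pos = np.array([next(it).split() for _ in range(n)], dtype=float)
        elif parts[0] == "POLYGONS":
            n = int(parts[1])
            rows = [next(it).split() for _ in range(n)]
            tris = np.array([r[1:4] for r in rows], dtype=np.int64)
        elif parts[0] == "box_length":
            box_length = float(next(it))
        elif parts[0] == "nominal_radius":
            nominal_radius = float(next(it))
    if pos is None or tris is None or box_length is None:
        raise ValueError(f"{path} is not a memtube VTK PolyData file")
    return TriMesh(pos, tris, box_length, nominal_radius or 0.0)


def write_mesh_off(mesh: TriMesh, path) -> None:
    p = Path(path)
    lines = [
        "OFF",
        f"# box_length={mesh.box_length!r} nominal_radius={mesh.nominal_radius!r}",
        f"{mesh.n_vertices} {mesh.n_triangles} {mesh.n_edges}",
    ]
    for x, y, z in mesh.positions:
        lines.append(f"{x:.17g} {y:.17g} {z:.17g}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    p.write_text("\n".join(lines) + "\n")


def read_mesh_off(path) -> TriMesh:
    raw = Path(path).read_text().splitlines()
    if not raw or raw[0].strip() != "OFF":
        raise ValueError(f"{path} is not an OFF file")
    box_length = 0.0
    nominal_radius = 0.0
    body = []
    for line in raw[1:]:
        s = line.strip()
        if s.startswith("#"):
            for tok in s[1:].split():
                if tok.startswith("box_length="):
                    box_length = float(tok.split("=", 1)[1])
                elif tok.startswith("nominal_radius="):
                    nominal_radius = float(tok.split("=", 1)[1])
            continue
        if s:
            body.append(s)
    nv, nf, _ = (int(x) for x in body[0].split())
    pos = np.array([body[1 + i].split() for i in range(nv)], dtype=float)
    tris = np.array([body[1 + nv + i].split()[1:4] for i in range(nf)],
                    dtype=np.int64)
    if box_length == 0.0:
        box_length = float(pos[:, 2].max() - pos[:, 2].min()) or 1.0
    return TriMesh(pos, tris, box_length, nominal_radius)


def write_snapshot(state, path, fmt: str = "vtk") -> list[Path]:
    """Write an MCState's mesh and protein spheres; returns written paths.

    The mesh goes to ``path``; protein spheres to ``<stem>_proteins.csv``
    (columns protein, sphere, x, y, z) plus a VTK point set when fmt=vtk.
    """
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; use one of {FORMATS}")
    p = Path(path)
    out = [p]
    if fmt == "vtk":
        write_mesh_vtk(state.mesh, p)
    else:
        write_mesh_off(state.mesh, p)
    sph = state.sphere_positions
    csv_path = p.with_name(p.stem + "_proteins.csv")
    with open(csv_path, "w") as f:
        f.write("protein,sphere,x,y,z\r\n")
        for i in range(sph.shape[0]):
            for s in range(sph.shape[1]):
                x, y, z = sph[i, s]
                f.write(f"{i},{s},{x:.17g},{y:.17g},{z:.17g}\r\n")
    out.append(csv_path)
    if fmt == "vtk":
        vp = p.with_name(p.stem + "_proteins.vtk")
        n = sph.shape[0] * sph.shape[1]
        lines = [
            "# vtk DataFile Version 3.0", "protein spheres", "ASCII",
            "DATASET POLYDATA", f"POINTS {n} double",
        ]
        for i in range(sph.shape[0]):
            for s in range(sph.shape[1]):
                x, y, z = sph[i, s]
                lines.append(f"{x:.17g} {y:.17g} {z:.17g}")
        lines += [f"VERTICES {n} {2 * n}"]
        lines += [f"1 {k}" for k in range(n)]
        lines += [f"POINT_DATA {n}", "SCALARS protein_id int 1",
                  "LOOKUP_TABLE default"]
        lines += [str(i) for i in range(sph.shape[0]) for _ in range(5)]
        lines += ["SCALARS sphere_index int 1", "LOOKUP_TABLE default"]
        lines += [str(s) for _ in range(sph.shape[0]) for s in range(5)]
        vp.write_text("\n".join(lines) + "\n")
        out.append(vp)
    return out


def read_snapshot(path) -> TriMesh:
    """Read a mesh snapshot written by ``write_snapshot`` (vtk or off)."""
    head = Path(path).read_text(encoding="utf-8", errors="replace")[:64]
    if head.startswith("# vtk"):
        return read_mesh_vtk(path)
    if head.startswith("OFF"):
        return read_mesh_off(path)
    raise ValueError(f"unsupported snapshot format in {path}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "scenario", "scale", "seed", "radius", "length", "n_proteins", "sweeps",
    "burn_in", "r_pr", "outdir", "formats", "log_level", "energy", "moves",
}
_ENERGY_KEYS = set(EnergyParams.__dataclass_fields__)
_MOVE_KEYS = set(MCParams.__dataclass_fields__)


@dataclass
class RunConfig:
    """Fully resolved run configuration; round-trips through YAML."""

    scenario: str = "low_density"
    scale: float = 1.0
    seed: int = 0
    radius: Optional[float] = None
    length: Optional[float] = None
    n_proteins: Optional[int] = None
    sweeps: Optional[int] = None
    burn_in: Optional[int] = None
    r_pr: Optional[float] = None
    outdir: str = "memtube_out"
    formats: tuple = ("vtk",)
    log_level: str = "INFO"
    energy: dict = field(default_factory=dict)
    moves: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        d = asdict(self)
        d["formats"] = list(self.formats)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for section, allowed in (("energy", _ENERGY_KEYS), ("moves", _MOVE_KEYS)):
        sub = raw.get(section) or {}
        bad = set(sub) - allowed
        if bad:
            raise ValueError(f"{path}: unknown {section} keys {sorted(bad)}")
    cfg = RunConfig(**{k: (tuple(v) if k == "formats" else v)
                       for k, v in raw.items()})
    # constructing the parameter objects validates the numeric ranges
    EnergyParams(**cfg.energy)
    MCParams(**{**cfg.moves, "seed": cfg.seed})
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))


def write_manifest(outdir, cfg: RunConfig, extra: Optional[dict] = None) -> Path:
    """Machine-readable provenance: config hash, seed, versions."""
    import numpy
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.resolved(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"memtube": __version__, "numpy": numpy.__version__},
    }
    manifest.update(extra or {})
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
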