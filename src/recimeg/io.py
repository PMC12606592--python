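"""Persistence and configuration: manifests, layouts, matrices, run configs.

Every persisted matrix artifact is a binary .npy container plus a
structured-text JSON sidecar carrying method, units, input hashes and
solver settings; readers re-validate the hashes so stale or mismatched
artifacts are rejected instead of silently consumed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bem import SolverConfig
from .geometry import ConductivityLayer, HeadModel, SourceSpace, read_mesh, write_mesh
from .leadfield import Leadfield

__all__ = [
    "write_head_manifest",
    "read_head_manifest",
    "save_leadfield",
    "load_leadfield",
    "save_source_space",
    "load_source_space",
    "RunConfig",
    "load_run_config",
    "sha256_of_array",
    "write_table",
]


def sha256_of_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Head manifest: one line per layer (outermost first)
# ---------------------------------------------------------------------------

_MANIFEST_HEADER = "name\tmesh_path\tsigma_inside\tsigma_outside"


def write_head_manifest(head: HeadModel, directory: str | Path,
                        mesh_format: str = ".ply") -> Path:
    """Write layer meshes + a tab-separated manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [_MANIFEST_HEADER]
    for lay in head.layers:
        mesh_name = f"{lay.name}{mesh_format}"
        write_mesh(lay.mesh, directory / mesh_name)
        lines.append(f"{lay.name}\t{mesh_name}\t{lay.sigma_inside!r}\t{lay.sigma_outside!r}")
    path = directory / "head_manifest.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def read_head_manifest(path: str | Path) -> HeadModel:
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if lines[0] != _MANIFEST_HEADER:
        raise ValueError("unrecognized head manifest header")
    layers = []
    for line in lines[1:]:
        name, mesh_path, s_in, s_out = line.split("\t")
        mesh_file = path.parent / mesh_path
        if not mesh_file.exists():
            raise FileNotFoundError(f"manifest references missing mesh {mesh_file}")
        layers.append(ConductivityLayer(read_mesh(mesh_file), float(s_in), float(s_out), name))
    return HeadModel(layers)


# ---------------------------------------------------------------------------
# Leadfield and source space containers
# ---------------------------------------------------------------------------

def save_source_space(src: SourceSpace, path: str | Path) -> None:
    np.savez(str(path),
             positions=src.positions, normals=src.normals,
             areas=src.areas, parent_face=src.parent_face)


def load_source_space(path: str | Path) -> SourceSpace:
    z = np.load(str(path))
    return SourceSpace(z["positions"], z["normals"], z["areas"], z["parent_face"])


def save_leadfield(lf: Leadfield, path: str | Path,
                   extra_meta: dict | None = None) -> None:
    """Matrix to <path>.npy, metadata sidecar to <path>.json."""
    path = Path(path)
    npy = path.with_suffix(".npy")
    np.save(npy, lf.matrix)
    meta = {
        "method": lf.method,
        "units": lf.units,
        "sensor_names": lf.sensor_names,
        "shape": list(lf.shape),
        "matrix_sha256": sha256_of_array(lf.matrix),
        "source_positions_sha256": sha256_of_array(lf.source_space.positions),
        "solve_count": lf.solve_count,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def load_leadfield(path: str | Path, source_space: SourceSpace) -> Leadfield:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    matrix = np.load(path.with_suffix(".npy"))
    if sha256_of_array(matrix) != meta["matrix_sha256"]:
        raise ValueError("leadfield matrix hash mismatch (stale or corrupted artifact)")
    if sha256_of_array(source_space.positions) != meta["source_positions_sha256"]:
        raise ValueError("source space does not match the stored leadfield")
    return Leadfield(matrix, meta["sensor_names"], source_space, meta["method"],
                     meta["units"], meta.get("solve_count", 0))


def verify_sidecar(path: str | Path) -> bool:
    """Re-validate the matrix hash of a stored container."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    matrix = np.load(path.with_suffix(".npy"))
    return sha256_of_array(matrix) == meta["matrix_sha256"]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline settings mirroring the module configs (YAML file)."""

    head_manifest: str = ""
    sensor_layout: str = ""
    output_dir: str = "out"
    solver: SolverConfig = field(default_factory=SolverConfig)
    snr_assumed: float = 3.0
    depth_exponent: float = 1.0
    diagonal_loading: float = 0.1
    localization_threshold: float = 0.75
    snr_levels: tuple = (81.0, 27.0, 9.0, 3.0, 2.0, 1.5)
    n_noise_dipoles: int = 200
    n_samples: int = 100
    seed: int = 0

    def validate_paths(self) -> None:
        for p in (self.head_manifest, self.sensor_layout):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    solver = SolverConfig(**raw.pop("solver", {}))
    if "snr_levels" in raw:
        raw["snr_levels"] = tuple(raw["snr_levels"])
    return RunConfig(solver=solver, **raw)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["snr_levels"] = list(cfg.snr_levels)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_table(rows: list[dict], path: str | Path) -> None:
    """Tab-separated table with a header from the union of row keys."""
    if not rows:
        Path(path).write_text("")
        return
    keys = list(rows[0].keys())
    lines = ["\t".join(keys)]
    for r in rows:
        lines.append("\t".join(str(r.get(k, "")) for k in keys))
    Path(path).write_text("\n".join(lines) + "\n")
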