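"""Triangulated conductor geometry: meshes, layered head models, source spaces.

All coordinates are in meters (SI throughout).  Meshes are face-indexed:
fields are collocated at triangle centers, matching the collocation
discretization used by the charge solver.  Outward normals point from the
higher-index (inner, ``sigma_inside``) medium toward the outer
(``sigma_outside``) medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "ConductivityLayer",
    "HeadModel",
    "SourceSpace",
    "build_icosphere",
    "build_sphere_head",
    "build_cortex_phantom",
    "build_evaluation_phantom",
    "fibonacci_tangential_sources",
    "source_space_from_mesh",
    "solid_angles",
    "points_inside",
    "face_mean_curvature",
    "read_mesh",
    "write_mesh",
    "conductivity_contrast",
]

#: Tissue conductivities (S/m) used for default phantoms.
CONDUCTIVITY = {
    "skin": 0.25,
    "skull": 0.01,
    "csf": 1.654,
    "gm": 0.275,
    "wm": 0.126,
}


def conductivity_contrast(sigma_inside: float, sigma_outside: float) -> float:
    """Conductivity contrast K = (sigma- - sigma+)/(sigma- + sigma+).

    ``sigma_inside`` is the conductivity just inside the surface (the side
    the outward normal points away from), ``sigma_outside`` just outside.
    """
    s = sigma_inside + sigma_outside
    if s <= 0:
        raise ValueError("conductivities must not both be zero")
    return (sigma_inside - sigma_outside) / s


@dataclass
class TriangleMesh:
    """A triangle surface mesh with per-face centers, normals and areas."""

    vertices: np.ndarray  # (V, 3) float, meters
    faces: np.ndarray     # (F, 3) int
    face_centers: np.ndarray = field(init=False)
    face_normals: np.ndarray = field(init=False)
    face_areas: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        tri = self.vertices[self.faces]  # (F, 3, 3)
        self.face_centers = tri.mean(axis=1)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        if np.any(norm <= 0):
            raise ValueError("degenerate (zero-area) face present")
        self.face_areas = 0.5 * norm
        self.face_normals = cross / norm[:, None]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Per-face vertex triples, shape (F, 3, 3)."""
        return self.vertices[self.faces]

    def signed_volume(self) -> float:
        """Signed enclosed volume; positive for closed, outward-oriented meshes."""
        tri = self.triangles
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0

    def is_edge_manifold(self) -> bool:
        """True when every edge is shared by exactly two faces (closed surface)."""
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def validate_closed(self) -> None:
        """Raise if the mesh is not a closed, outward-oriented 2-manifold."""
        if not self.is_edge_manifold():
            raise ValueError("mesh is not edge-manifold (open or non-manifold surface)")
        if self.signed_volume() <= 0:
            raise ValueError("mesh is not outward oriented (signed volume <= 0)")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class ConductivityLayer:
    """A closed interface surface with conductivities on both sides (S/m)."""

    mesh: TriangleMesh
    sigma_inside: float
    sigma_outside: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma_inside < 0 or self.sigma_outside < 0:
            raise ValueError("conductivities must be non-negative")
        if self.sigma_inside == 0 and self.sigma_outside == 0:
            raise ValueError("conductivities must not both be zero")

    @property
    def contrast(self) -> float:
        return conductivity_contrast(self.sigma_inside, self.sigma_outside)


class HeadModel:
    """An ordered collection of conductivity interfaces (outermost first).

    Faces of all layers are concatenated into flat per-face arrays; the
    per-face conductivity contrast K drives charge induction at each
    interface.  Layer nesting is not required (non-nested topologies are
    supported): each surface only carries its own two-sided conductivities.
    """

    def __init__(self, layers: list[ConductivityLayer]):
        if not layers:
            raise ValueError("head model needs at least one layer")
        self.layers = list(layers)
        counts = [lay.mesh.n_faces for lay in self.layers]
        self._offsets = np.concatenate([[0], np.cumsum(counts)])
        self.face_centers = np.concatenate([lay.mesh.face_centers for lay in self.layers])
        self.face_normals = np.concatenate([lay.mesh.face_normals for lay in self.layers])
        self.face_areas = np.concatenate([lay.mesh.face_areas for lay in self.layers])
        self.contrast = np.concatenate(
            [np.full(lay.mesh.n_faces, lay.contrast) for lay in self.layers]
        )
        # sigma- - sigma+ per face, the weight of the Geselowitz surface term
        self.sigma_jump = np.concatenate(
            [np.full(lay.mesh.n_faces, lay.sigma_inside - lay.sigma_outside) for lay in self.layers]
        )

    @property
    def total_faces(self) -> int:
        return int(self._offsets[-1])

    @property
    def triangles(self) -> np.ndarray:
        return np.concatenate([lay.mesh.triangles for lay in self.layers])

    def layer_slice(self, name: str) -> slice:
        for i, lay in enumerate(self.layers):
            if lay.name == name:
                return slice(int(self._offsets[i]), int(self._offsets[i + 1]))
        raise KeyError(f"no layer named {name!r}")

    def layer(self, name: str) -> ConductivityLayer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(f"no layer named {name!r}")


@dataclass
class SourceSpace:
    """Dipole locations with fixed (normal) orientations.

    One entry per selected face of a cortical surface; positions sit a small
    ``shift`` outside the parent face centers along the face normal, and
    orientations inherit the surface's outward normal.
    """

    positions: np.ndarray   # (N, 3) m
    normals: np.ndarray     # (N, 3) unit vectors
    areas: np.ndarray       # (N,) m^2
    parent_face: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.parent_face = np.asarray(self.parent_face, dtype=np.int64)
        n = len(self.positions)
        if not (len(self.normals) == len(self.areas) == len(self.parent_face) == n):
            raise ValueError("source space field lengths disagree")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("source orientations must be unit vectors")

    @property
    def n_sources(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# Phantom generators
# ---------------------------------------------------------------------------

def build_icosphere(radius: float, subdivisions: int) -> TriangleMesh:
    """Closed, outward-oriented icosphere with 20 * 4**subdivisions faces."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def build_sphere_head(
    radii: list[float],
    conductivities: list[float],
    subdivisions: int | list[int] = 3,
    names: list[str] | None = None,
) -> HeadModel:
    """Nested-sphere head model, outermost first.

    ``conductivities[i]`` is the conductivity of the medium immediately
    inside surface ``i``; the medium outside surface ``i`` is the one inside
    surface ``i-1`` (vacuum outside the outermost surface).
    """
    radii = list(radii)
    conductivities = list(conductivities)
    if len(radii) != len(conductivities):
        raise ValueError("radii and conductivities must have equal length")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing (outermost first)")
    if isinstance(subdivisions, int):
        subdivisions = [subdivisions] * len(radii)
    if names is None:
        names = [f"layer{i}" for i in range(len(radii))]
    layers = []
    sigma_out = 0.0
    for r, sig, sub, name in zip(radii, conductivities, subdivisions, names):
        mesh = build_icosphere(r, sub)
        layers.append(ConductivityLayer(mesh, sigma_inside=sig, sigma_outside=sigma_out, name=name))
        sigma_out = sig
    return HeadModel(layers)


def _fold_radii(vertices: np.ndarray, amplitude_rel: float, frequency: int, phase: float) -> np.ndarray:
    """Radial modulation factor 1 + a*sin(k*theta)*sin(k*(phi+phi0)) per vertex."""
    r = np.linalg.norm(vertices, axis=1)
    theta = np.arccos(np.clip(vertices[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(vertices[:, 1], vertices[:, 0])
    return 1.0 + amplitude_rel * np.sin(frequency * theta) * np.sin(frequency * (phi + phase))


def build_cortex_phantom(
    base_radius: float,
    fold_amplitude: float,
    fold_frequency: int = 6,
    subdivisions: int = 4,
    seed: int = 0,
    thickness: float = 0.003,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Cortex-like phantom: radially folded "WM" and "GM" sphere pair.

    Both surfaces share the fold field r(theta, phi) = R (1 + a sin(k theta)
    sin(k (phi + phi0))), with the GM surface offset outward by ``thickness``
    along the radius.  Sulcal valleys and gyral crowns appear once
    a * k**2 > 1 (mean curvature changes sign).  The azimuthal phase phi0 is
    drawn from ``seed``, so a fixed seed reproduces the meshes exactly.
    """
    if fold_amplitude >= base_radius / 4:
        raise ValueError("fold_amplitude must be below base_radius/4")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi))
    a = fold_amplitude / base_radius

    out = []
    for radius in (base_radius, base_radius + thickness):
        sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        verts = np.asarray(sphere.vertices)
        factor = _fold_radii(verts, a, fold_frequency, phase)
        mesh = TriangleMesh(verts * (radius * factor)[:, None], np.asarray(sphere.faces))
        mesh.validate_closed()
        out.append(mesh)
    wm, gm = out
    # star-shaped surfaces with a common fold field and a positive radial
    # offset cannot intersect; verify radial ordering as a guard anyway
    r_wm = np.linalg.norm(wm.vertices, axis=1)
    r_gm = np.linalg.norm(gm.vertices, axis=1)
    if not np.all(r_gm > r_wm):
        raise ValueError("generated WM/GM surfaces intersect")
    return wm, gm


def fibonacci_tangential_sources(radius: float, n: int) -> SourceSpace:
    """Quasi-uniform tangentially oriented unit dipoles on a sphere shell.

    Positions follow a Fibonacci spiral; orientations are the local azimuthal
    tangent.  Radially oriented dipoles are magnetically silent inside nested
    spheres, so tangential orientations are the informative choice for
    forward-model comparisons on sphere phantoms.
    """
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    phi = golden * i
    pos = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    tang = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(n)])
    tang -= (np.einsum("ij,ij->i", tang, pos) / radius**2)[:, None] * pos
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    return SourceSpace(pos, tang, np.full(n, 4 * np.pi * radius**2 / n), np.arange(n))


def build_evaluation_phantom(
    cortex_base_radius: float = 0.062,
    fold_amplitude: float = 0.011,
    fold_frequency: int = 8,
    cortex_subdivisions: int = 4,
    shell_subdivisions: int = 2,
    source_depth: float = 0.008,
    seed: int = 0,
) -> tuple[HeadModel, SourceSpace]:
    """Four-layer localization phantom: skin/skull/CSF spheres + folded cortex.

    The cortical boundary is a radially folded sphere whose sulcal walls
    carry strongly tangential face normals; one source per cortical face is
    placed ``source_depth`` radially inward (clearance from the surface of
    the order of the face size, which the unrefined direct forward path
    requires) and oriented along the folded surface's outward normal.
    """
    cortex, _ = build_cortex_phantom(cortex_base_radius, fold_amplitude,
                                     fold_frequency, cortex_subdivisions, seed=seed)
    layers = [
        ConductivityLayer(build_icosphere(0.090, shell_subdivisions),
                          CONDUCTIVITY["skin"], 0.0, "skin"),
        ConductivityLayer(build_icosphere(0.085, shell_subdivisions),
                          CONDUCTIVITY["skull"], CONDUCTIVITY["skin"], "skull"),
        ConductivityLayer(build_icosphere(0.080, shell_subdivisions),
                          CONDUCTIVITY["csf"], CONDUCTIVITY["skull"], "csf"),
        ConductivityLayer(cortex, CONDUCTIVITY["gm"], CONDUCTIVITY["csf"], "cortex"),
    ]
    head = HeadModel(layers)
    c = cortex.face_centers
    r = np.linalg.norm(c, axis=1)
    positions = c * (1.0 - source_depth / r)[:, None]
    src = SourceSpace(positions, cortex.face_normals.copy(),
                      cortex.face_areas.copy(), np.arange(cortex.n_faces))
    return head, src


def source_space_from_mesh(
    cortex: TriangleMesh,
    shift: float = 0.0005,
    enclosing: TriangleMesh | None = None,
) -> SourceSpace:
    """One dipole per face at face_center + shift * normal, normal-oriented.

    ``shift`` (default 0.5 mm) displaces the sources a small distance off the
    surface in the outward-normal direction (the side the charge shortcut
    evaluates).  When ``enclosing`` is given, sources must stay inside it.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    positions = cortex.face_centers + shift * cortex.face_normals
    if enclosing is not None:
        if not np.all(points_inside(enclosing, positions)):
            raise ValueError("shift pushes sources outside the enclosing surface")
    return SourceSpace(
        positions=positions,
        normals=cortex.face_normals.copy(),
        areas=cortex.face_areas.copy(),
        parent_face=np.arange(cortex.n_faces),
    )


def solid_angles(triangles: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Signed solid angle of each triangle seen from each point, shape (P, F).

    Van Oosterom-Strackee formula; positive when the outward normal faces
    away from the point.
    """
    out = np.empty((len(points), len(triangles)))
    for pi, p in enumerate(np.atleast_2d(points)):
        r = triangles - p  # (F, 3, 3)
        n = np.linalg.norm(r, axis=2)
        num = np.einsum("fk,fk->f", r[:, 0], np.cross(r[:, 1], r[:, 2]))
        den = (n[:, 0] * n[:, 1] * n[:, 2]
               + np.einsum("fk,fk->f", r[:, 0], r[:, 1]) * n[:, 2]
               + np.einsum("fk,fk->f", r[:, 0], r[:, 2]) * n[:, 1]
               + np.einsum("fk,fk->f", r[:, 1], r[:, 2]) * n[:, 0])
        out[pi] = 2.0 * np.arctan2(num, den)
    return out


def points_inside(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Winding-number containment test for a closed, outward-oriented mesh."""
    w = solid_angles(mesh.triangles, np.atleast_2d(points)).sum(axis=1)
    return w > 2.0 * np.pi  # 4 pi inside, 0 outside


# ---------------------------------------------------------------------------
# Discrete curvature
# ---------------------------------------------------------------------------

def face_mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Discrete mean curvature H per face (1/m), positive on convex surfaces.

    Per-vertex curvature from the cotangent Laplace-Beltrami operator
    (mean-curvature normal), signed by the outward vertex normal, then
    averaged onto faces.  A sphere of radius r yields H ~ +1/r everywhere;
    sulcal valleys carry negative H.
    """
    V = mesh.vertices
    F = mesh.faces
    nv = len(V)
    lap = np.zeros((nv, 3))
    wsum = np.zeros(nv)
    area_v = np.zeros(nv)
    vnorm = np.zeros((nv, 3))

    tri = V[F]
    for i in range(3):
        # angle at vertex i of each face, opposite edge (j, k)
        j, k = (i + 1) % 3, (i + 2) % 3
        e1 = tri[:, j] - tri[:, i]
        e2 = tri[:, k] - tri[:, i]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        # cot(angle at i) weights edge (j, k); both adjacent faces accumulate
        for a, b in ((j, k), (k, j)):
            np.add.at(lap, F[:, a], cot[:, None] * (V[F[:, b]] - V[F[:, a]]))
            np.add.at(wsum, F[:, a], cot)
    fa = mesh.face_areas
    fn = mesh.face_normals
    for i in range(3):
        np.add.at(area_v, F[:, i], fa / 3.0)
        np.add.at(vnorm, F[:, i], fa[:, None] * fn)

    # mean-curvature normal: (1/(2 A_v)) * sum cot-weighted edges = -2 H n
    hn = lap / (2.0 * area_v[:, None])
    sign = -np.sign(np.einsum("ij,ij->i", hn, vnorm))
    h_vertex = sign * 0.5 * np.linalg.norm(hn, axis=1)
    return h_vertex[F].mean(axis=1)


# ---------------------------------------------------------------------------
# Mesh file I/O (STL / OFF / PLY via trimesh)
# ---------------------------------------------------------------------------

_MESH_EXT = {".stl", ".off", ".ply"}


def read_mesh(path: str | Path) -> TriangleMesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use STL/OFF/PLY)")
    m = trimesh.load_mesh(str(path), process=False)
    return TriangleMesh(np.asarray(m.vertices, dtype=float), np.asarray(m.faces))


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXT:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use STL/OFF/PLY)")
    mesh.as_trimesh().export(str(path))
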