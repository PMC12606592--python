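"""MEG sensor models: coils as flux integrators and as induction coils.

Each sensor is described by one (magnetometer) or two (planar gradiometer)
rectangular pickup loops.  For the forward flux computation the loops carry a
tensor-product quadrature rule; for the reciprocal computation the loop
outlines are discretized into current elements whose aggregate free-space
field is the primary (incident) E-field of the sensor driven as an induction
coil.

Loop outlines are wound right-handed about the loop normal.  The two coils
of a planar gradiometer are wound with opposed normals (+n, -n), so a
uniform field is rejected, and the flux difference divided by the baseline
and the single-loop area yields a field gradient in T/m.  Magnetometer
outputs are flux divided by loop area (T).

The drive waveform slope dI/dt is 1 A/s by default; the operating frequency
is arbitrary in the quasi-static regime, so it is fixed such that
dI/dt = I0 * omega = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CurrentElement",
    "Sensor",
    "SensorArray",
    "discretize_loop",
    "primary_E",
    "flux_quadrature",
    "sensor_output_from_B",
    "build_helmet_array",
    "write_sensor_layout",
    "read_sensor_layout",
]

MU0 = 4e-7 * np.pi  # N/A^2, permeability of free space

#: Representative coil dimensions (m); VectorView-like but configurable.
DEFAULT_MAG_SIDE = 0.021
DEFAULT_GRAD_SIDE = 0.010
DEFAULT_GRAD_BASELINE = 0.0168


@dataclass
class CurrentElement:
    """A straight current element: center, direction (length = arc length), dI/dt."""

    center: np.ndarray    # (3,) m
    direction: np.ndarray  # (3,) m, |direction| = element arc length
    dIdt: float = 1.0      # A/s

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if not np.all(np.isfinite(self.direction)) or np.linalg.norm(self.direction) == 0:
            raise ValueError("element direction must be finite and nonzero")


def _rect_outline(center: np.ndarray, t1: np.ndarray, t2: np.ndarray, side: float) -> np.ndarray:
    """Corners of a square loop in the (t1, t2) plane, wound right-handed
    about n = t1 x t2."""
    h = side / 2.0
    return np.array(
        [center + h * (s1 * t1 + s2 * t2) for s1, s2 in ((-1, -1), (1, -1), (1, 1), (-1, 1))]
    )


def discretize_loop(outline: np.ndarray, n_elements: int = 32, dIdt: float = 1.0) -> list[CurrentElement]:
    """Split a closed polygonal loop into uniform-arc-length current elements.

    The outline is the ordered corner list of a closed loop (last corner
    connects back to the first).  Element directions telescope to zero and
    their lengths partition the perimeter.
    """
    outline = np.asarray(outline, dtype=float)
    if n_elements < 8:
        raise ValueError("need at least 8 elements per loop")
    if len(outline) < 3:
        raise ValueError("open outline: a closed loop needs >= 3 corners")
    seg_vec = np.roll(outline, -1, axis=0) - outline
    seg_len = np.linalg.norm(seg_vec, axis=1)
    perimeter = seg_len.sum()
    if perimeter == 0:
        raise ValueError("degenerate outline")
    # distribute elements over segments proportionally to length, >= 1 each
    counts = np.maximum(1, np.round(n_elements * seg_len / perimeter).astype(int))
    elements: list[CurrentElement] = []
    for p0, vec, cnt in zip(outline, seg_vec, counts):
        for k in range(cnt):
            t0, t1 = k / cnt, (k + 1) / cnt
            elements.append(CurrentElement(p0 + 0.5 * (t0 + t1) * vec, (t1 - t0) * vec, dIdt))
    return elements


def primary_E(elements: list[CurrentElement], points: np.ndarray) -> np.ndarray:
    """Free-space E-field of current elements driven at their dI/dt.

    E(r) = -sum_j (dI_j/dt) (mu0 / 4 pi) s_j / |r - p_j|   (V/m per A/s)
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.array([e.center for e in elements])
    sdir = np.array([e.direction * e.dIdt for e in elements])
    diff = points[:, None, :] - centers[None, :, :]  # (P, L, 3)
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist == 0):
        raise ValueError("evaluation point coincides with a current element center")
    return -(MU0 / (4 * np.pi)) * np.einsum("pl,lk->pk", 1.0 / dist, sdir)


@dataclass
class Sensor:
    """A pickup coil: one loop (magnetometer) or an opposed pair (gradiometer)."""

    name: str
    kind: str  # "magnetometer" | "planar_gradiometer"
    loops: list[np.ndarray]          # corner arrays (4, 3), right-handed winding
    loop_normals: list[np.ndarray]   # unit normal per loop (gradiometer: +n, -n)
    baseline: float = 0.0            # m, gradiometer coil separation
    n_elements: int = 32             # current elements per loop
    layout: dict = field(default=None, repr=False)  # construction params, for exact file round-trips
    quad_points: np.ndarray = field(default=None, repr=False)
    quad_weights: np.ndarray = field(default=None, repr=False)
    quad_loop: np.ndarray = field(default=None, repr=False)  # loop index per quad point

    def __post_init__(self) -> None:
        if self.kind not in ("magnetometer", "planar_gradiometer"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if self.kind == "planar_gradiometer":
            if len(self.loops) != 2 or self.baseline <= 0:
                raise ValueError("gradiometer needs two loops and a positive baseline")
        elif len(self.loops) != 1:
            raise ValueError("magnetometer has exactly one loop")
        if self.quad_points is None:
            n = 64 * len(self.loops)
            self.quad_points, self.quad_weights, self.quad_loop = flux_quadrature(self, n)

    @property
    def elements(self) -> list[CurrentElement]:
        """Current elements of all loops, wound per the stated loop normals."""
        out: list[CurrentElement] = []
        for outline in self.loops:
            out.extend(discretize_loop(outline, self.n_elements, dIdt=1.0))
        return out

    @property
    def loop_area(self) -> float:
        """Area of a single loop (m^2)."""
        c = self.loops[0]
        return float(
            0.5 * np.linalg.norm(
                sum(np.cross(c[i], c[(i + 1) % len(c)]) for i in range(len(c)))
            )
        )

    @property
    def center(self) -> np.ndarray:
        return np.mean([lo.mean(axis=0) for lo in self.loops], axis=0)


def flux_quadrature(sensor: Sensor, n_points: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tensor-grid midpoint rule over each loop; weights sum to loop area.

    ``n_points`` is the total count; it must split into a perfect square per
    loop (64 per magnetometer loop and 64 per gradiometer coil by default,
    i.e. 128 observation points per gradiometer).
    """
    per_loop = n_points // len(sensor.loops)
    k = int(round(np.sqrt(per_loop)))
    if k * k != per_loop or per_loop < 1:
        raise ValueError("n_points must be a perfect square per loop")
    pts, wts, loop_ix = [], [], []
    for ix, corners in enumerate(sensor.loops):
        origin = corners[0]
        e1 = corners[1] - corners[0]
        e2 = corners[3] - corners[0]
        area = float(np.linalg.norm(np.cross(e1, e2)))
        if area == 0:
            raise ValueError("degenerate (zero-area) loop")
        u = (np.arange(k) + 0.5) / k
        U, V = np.meshgrid(u, u, indexing="ij")
        grid = origin + U.ravel()[:, None] * e1 + V.ravel()[:, None] * e2
        pts.append(grid)
        wts.append(np.full(k * k, area / (k * k)))
        loop_ix.append(np.full(k * k, ix, dtype=int))
    return np.concatenate(pts), np.concatenate(wts), np.concatenate(loop_ix)


def sensor_output_from_B(B_at_points: np.ndarray, sensor: Sensor) -> float:
    """Sensor reading from B sampled at the sensor's quadrature points.

    Magnetometer: flux / loop area  (T).  Planar gradiometer: opposed-normal
    flux sum / (baseline * loop area)  (T/m).
    """
    B = np.asarray(B_at_points, dtype=float)
    if B.shape != sensor.quad_points.shape:
        raise ValueError("B must be sampled at the sensor's quad_points")
    normals = np.array([sensor.loop_normals[i] for i in sensor.quad_loop])
    flux = float(np.sum(sensor.quad_weights * np.einsum("ij,ij->i", B, normals)))
    if sensor.kind == "magnetometer":
        return flux / sensor.loop_area
    return flux / (sensor.baseline * sensor.loop_area)


@dataclass
class SensorArray:
    sensors: list[Sensor]

    def __post_init__(self) -> None:
        if not self.sensors:
            raise ValueError("sensor array must be nonempty")
        names = [s.name for s in self.sensors]
        if len(set(names)) != len(names):
            raise ValueError("sensor names must be unique")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sensors]

    def __len__(self) -> int:
        return len(self.sensors)

    def __iter__(self):
        return iter(self.sensors)


def _site_frame(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tangents orthogonal to n (deterministic)."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v if abs(n - 1.0) <= 1e-12 else v / n


def make_magnetometer(name: str, center: np.ndarray, normal: np.ndarray,
                      side: float = DEFAULT_MAG_SIDE, n_elements: int = 32) -> Sensor:
    normal = _unit(np.asarray(normal, float))
    t1, t2 = _site_frame(normal)
    center = np.asarray(center, float)
    return Sensor(name, "magnetometer", [_rect_outline(center, t1, t2, side)],
                  [normal], n_elements=n_elements,
                  layout={"center": center, "normal": normal, "axis": np.zeros(3),
                          "side": side, "baseline": 0.0})


def make_planar_gradiometer(name: str, center: np.ndarray, normal: np.ndarray,
                            grad_axis: np.ndarray, side: float = DEFAULT_GRAD_SIDE,
                            baseline: float = DEFAULT_GRAD_BASELINE,
                            n_elements: int = 32) -> Sensor:
    """Opposed coil pair separated by ``baseline`` along ``grad_axis``."""
    normal = _unit(np.asarray(normal, float))
    axis = np.asarray(grad_axis, float)
    dot = axis @ normal
    if abs(dot) > 1e-12:  # keep idempotent for already-orthogonal input
        axis = axis - dot * normal
    axis = _unit(axis)
    t2 = np.cross(normal, axis)
    c = np.asarray(center, float)
    loop1 = _rect_outline(c + 0.5 * baseline * axis, axis, t2, side)       # normal +n
    loop2 = _rect_outline(c - 0.5 * baseline * axis, t2, axis, side)       # normal -n
    return Sensor(name, "planar_gradiometer", [loop1, loop2], [normal, -normal],
                  baseline=baseline, n_elements=n_elements,
                  layout={"center": c, "normal": normal, "axis": axis,
                          "side": side, "baseline": baseline})


def build_helmet_array(
    n_sites: int,
    shell_radius: float,
    coverage: float = 0.4,
    kinds: tuple[str, ...] = ("magnetometer", "planar_gradiometer", "planar_gradiometer"),
    head_radius: float = 0.0,
    n_elements: int = 32,
) -> SensorArray:
    """Helmet-like array: sensor sites quasi-uniform over a spherical cap.

    Sites are spread by a Fibonacci spiral over the cap around +z covering
    ``coverage`` of the full solid angle.  Each site hosts a magnetometer
    and/or two orthogonal planar gradiometers tangential to the cap,
    following the triplet layout of whole-head MEG systems.
    """
    if shell_radius <= head_radius:
        raise ValueError("shell_radius must exceed the outermost head radius")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zmin = 1.0 - 2.0 * coverage  # cap: z in [zmin, 1]
    sensors: list[Sensor] = []
    for i in range(n_sites):
        z = 1.0 - (i + 0.5) / n_sites * (1.0 - zmin)
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        phi = golden * i
        n = np.array([rho * np.cos(phi), rho * np.sin(phi), z])
        center = shell_radius * n
        t1, t2 = _site_frame(n)
        n_grad = 0
        for kind in kinds:
            if kind == "magnetometer":
                sensors.append(make_magnetometer(f"MAG{i:03d}", center, n, n_elements=n_elements))
            elif kind == "planar_gradiometer":
                axis = t1 if n_grad == 0 else t2
                sensors.append(make_planar_gradiometer(
                    f"GRAD{i:03d}{'xy'[n_grad]}", center, n, axis, n_elements=n_elements))
                n_grad += 1
            else:
                raise ValueError(f"unknown sensor kind {kind!r}")
    return SensorArray(sensors)


# ---------------------------------------------------------------------------
# Layout file I/O (tab-separated; exact round-trip via repr floats)
# ---------------------------------------------------------------------------

_LAYOUT_HEADER = (
    "name\tkind\tcx\tcy\tcz\tnx\tny\tnz\tax\tay\taz\tside\tbaseline\tn_elements"
)


def write_sensor_layout(array: SensorArray, path: str | Path) -> None:
    lines = [_LAYOUT_HEADER]
    for s in array:
        if s.layout is not None:
            c, n, axis = s.layout["center"], s.layout["normal"], s.layout["axis"]
            side, baseline = s.layout["side"], s.layout["baseline"]
        else:
            c, n = s.center, s.loop_normals[0]
            side = float(np.linalg.norm(s.loops[0][1] - s.loops[0][0]))
            baseline = s.baseline
            if s.kind == "planar_gradiometer":
                axis = s.loops[0].mean(axis=0) - s.loops[1].mean(axis=0)
                axis /= np.linalg.norm(axis)
            else:
                axis = np.zeros(3)
        vals = [s.name, s.kind] + [repr(float(v)) for v in (*c, *n, *axis, side, baseline)] \
            + [str(s.n_elements)]
        lines.append("\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sensor_layout(path: str | Path) -> SensorArray:
    lines = Path(path).read_text().strip().splitlines()
    if lines[0] != _LAYOUT_HEADER:
        raise ValueError("unrecognized sensor layout header")
    sensors = []
    for line in lines[1:]:
        f = line.split("\t")
        name, kind = f[0], f[1]
        c = np.array([float(v) for v in f[2:5]])
        n = np.array([float(v) for v in f[5:8]])
        axis = np.array([float(v) for v in f[8:11]])
        side, baseline = float(f[11]), float(f[12])
        n_el = int(f[13])
        if kind == "magnetometer":
            sensors.append(make_magnetometer(name, c, n, side=side, n_elements=n_el))
        else:
            sensors.append(make_planar_gradiometer(name, c, n, axis, side=side,
                                                   baseline=baseline, n_elements=n_el))
    return SensorArray(sensors)
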