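"""Gain (leadfield) matrix assembly: reciprocal rows and direct columns.

The M x N gain matrix maps fixed-orientation dipole strengths (A m) to
sensor outputs (T for magnetometers, T/m for planar gradiometers).

Reciprocal (row-wise) path: each sensor is driven as an induction coil with
unit dI/dt; the induced total E-field at the source locations, projected on
the source orientations, fills an entire row with a single charge solve.
With loop outlines wound right-handed about the coil normal, Lorentz
reciprocity gives  flux(dipole -> coil) = - p . E_coil(r_dipole), hence the
global minus sign below; the flux is converted to the sensor's output units
by the same loop-area (and baseline) normalization the flux integrator
uses.

Direct (column-wise) path: for each dipole, solve the charge problem driven
by the dipole's primary field, evaluate B at the sensor quadrature points as
the primary (Biot-Savart) term plus the volume-current surface term

    B_v(r) = -(mu0 / 4 pi) sum_faces (sigma_in - sigma_out) A_m phi_m
             n_m x (r - r_m) / |r - r_m|^3,

with phi the total surface potential, and integrate the flux per sensor.

The Sarvas closed form for a dipole in a spherically symmetric conductor
serves as the analytic method and validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bem import (ChargeOperator, SolverConfig, E_total_at_points,
                  solve_charges, surface_potential)
from .geometry import HeadModel, SourceSpace
from .sensors import MU0, Sensor, SensorArray, primary_E, sensor_output_from_B

__all__ = [
    "Leadfield",
    "reciprocal_row",
    "direct_column",
    "sarvas_field",
    "assemble_leadfield",
    "dipole_primary_E",
    "dipole_primary_potential",
    "dipole_primary_B",
]


@dataclass
class Leadfield:
    """Gain matrix with its provenance (method, units per sensor kind)."""

    matrix: np.ndarray          # (M, N), sensor output per unit dipole (A m)
    sensor_names: list[str]
    source_space: SourceSpace
    method: str                 # "reciprocal" | "direct" | "analytic"
    units: list[str] = field(default_factory=list)  # per-sensor ("T" | "T/m")
    solve_count: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sensor_names), self.source_space.n_sources):
            raise ValueError("leadfield shape does not match sensors/sources")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _sensor_scale(sensor: Sensor) -> float:
    """Flux -> output-unit conversion matching sensor_output_from_B."""
    if sensor.kind == "magnetometer":
        return sensor.loop_area
    return sensor.baseline * sensor.loop_area


def reciprocal_row(
    head: HeadModel,
    sensor: Sensor,
    source_space: SourceSpace,
    config: SolverConfig | None = None,
    operator: ChargeOperator | None = None,
    cortical_surface: str | None = None,
) -> np.ndarray:
    """One gain-matrix row via a single sensor-driven charge solve.

    When ``cortical_surface`` names a contrast-carrying layer whose faces
    are the source parents, the normal E-field is read directly from that
    surface's charge density (no secondary-field evaluation).  Otherwise the
    total E-field is evaluated at the source positions (general path, valid
    for arbitrary source orientations and zero-contrast test surfaces).
    """
    op = operator or ChargeOperator(head, config)
    elements = sensor.elements
    E_inc_faces = primary_E(elements, head.face_centers)
    sol = solve_charges(head, E_inc_faces, operator=op)
    if cortical_surface is not None:
        from .bem import normal_E_from_charge
        nE = normal_E_from_charge(head, sol.rho, cortical_surface, side="outside")
        row = nE[source_space.parent_face]
    else:
        E_src = E_total_at_points(head, sol.rho, primary_E(elements, source_space.positions),
                                  source_space.positions, operator=op)
        row = np.einsum("ij,ij->i", source_space.normals, E_src)
    return -row / _sensor_scale(sensor)


def dipole_primary_E(position: np.ndarray, moment: np.ndarray, sigma: float,
                     points: np.ndarray) -> np.ndarray:
    """Primary E-field of a current dipole in an infinite medium (V/m)."""
    d = np.atleast_2d(points) - position
    r = np.linalg.norm(d, axis=1)
    return (3 * (d @ moment)[:, None] * d / r[:, None] ** 5
            - moment[None, :] / r[:, None] ** 3) / (4 * np.pi * sigma)


def dipole_primary_potential(position: np.ndarray, moment: np.ndarray, sigma: float,
                             points: np.ndarray) -> np.ndarray:
    """Primary potential of a current dipole in an infinite medium (V)."""
    d = np.atleast_2d(points) - position
    r = np.linalg.norm(d, axis=1)
    return (d @ moment) / (4 * np.pi * sigma * r**3)


def dipole_primary_B(position: np.ndarray, moment: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Biot-Savart field of a current dipole in free space (T)."""
    d = np.atleast_2d(points) - position
    r = np.linalg.norm(d, axis=1)
    return (MU0 / (4 * np.pi)) * np.cross(np.broadcast_to(moment, d.shape), d) / r[:, None] ** 3


def _volume_current_B(op: ChargeOperator, head: HeadModel, phi: np.ndarray,
                      points: np.ndarray) -> np.ndarray:
    """Volume-current (surface-integral) contribution to B at points (T)."""
    w = head.sigma_jump * head.face_areas * phi      # (N,)
    diff = points[:, None, :] - op.centers[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    cross = np.cross(np.broadcast_to(op.normals[None, :, :], diff.shape), diff)
    return -(MU0 / (4 * np.pi)) * np.einsum("m,pmk,pm->pk", w, cross, 1.0 / dist**3)


def direct_column(
    head: HeadModel,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    sensors: SensorArray,
    config: SolverConfig | None = None,
    operator: ChargeOperator | None = None,
    sigma_dipole: float | None = None,
) -> np.ndarray:
    """One gain-matrix column: dipole-driven forward solve to all sensors.

    ``sigma_dipole`` is the conductivity of the compartment containing the
    dipole (defaults to the innermost layer's interior conductivity).
    """
    op = operator or ChargeOperator(head, config)
    pos = np.asarray(dipole_position, dtype=float)
    mom = np.asarray(dipole_moment, dtype=float)
    if sigma_dipole is None:
        sigma_dipole = head.layers[-1].sigma_inside
    if np.linalg.norm(mom) == 0.0:
        return np.zeros(len(sensors))
    E_inc = dipole_primary_E(pos, mom, sigma_dipole, head.face_centers)
    sol = solve_charges(head, E_inc, operator=op)
    phi_inc = dipole_primary_potential(pos, mom, sigma_dipole, head.face_centers)
    phi = surface_potential(head, sol.rho, phi_inc, operator=op)
    out = np.empty(len(sensors))
    for i, sensor in enumerate(sensors):
        pts = sensor.quad_points
        B = dipole_primary_B(pos, mom, pts) + _volume_current_B(op, head, phi, pts)
        out[i] = sensor_output_from_B(B, sensor)
    return out


def sarvas_field(dipole_position: np.ndarray, dipole_moment: np.ndarray,
                 sphere_center: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Closed-form B of a current dipole in a spherically symmetric conductor.

    Valid outside the conductor; independent of the (radial) conductivity
    profile.  Radial dipoles are magnetically silent.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - sphere_center
    r0 = np.asarray(dipole_position, dtype=float) - sphere_center
    Q = np.asarray(dipole_moment, dtype=float)
    a_vec = pts - r0
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(pts, axis=1)
    # F = a (r a + r^2 - r0 . r)
    r0_dot_r = pts @ r0
    F = a * (r * a + r**2 - r0_dot_r)
    if np.any(np.abs(F) < 1e-300):
        raise ValueError("degenerate geometry (F = 0) in closed-form evaluation")
    a_dot_r = np.einsum("ij,ij->i", a_vec, pts)
    gradF = ((a**2 / r + a_dot_r / a + 2 * a + 2 * r)[:, None] * pts
             - (a + 2 * r + a_dot_r / a)[:, None] * r0[None, :])
    Qxr0 = np.cross(Q, r0)
    B = (MU0 / (4 * np.pi * F**2))[:, None] * (
        F[:, None] * Qxr0[None, :] - (pts @ Qxr0)[:, None] * gradF)
    return B


def assemble_leadfield(
    head: HeadModel,
    sensors: SensorArray,
    source_space: SourceSpace,
    method: str = "reciprocal",
    config: SolverConfig | None = None,
    cortical_surface: str | None = None,
    sphere_center: np.ndarray | None = None,
    progress: bool = False,
) -> Leadfield:
    """Assemble the full M x N gain matrix by the requested method.

    ``reciprocal`` performs exactly M charge solves (one per sensor);
    ``direct`` performs N (one per dipole); ``analytic`` (homogeneous
    sphere) performs none.  Rows/columns are independent, so the assembly
    order is irrelevant.
    """
    M, N = len(sensors), source_space.n_sources
    matrix = np.empty((M, N))
    units = ["T" if s.kind == "magnetometer" else "T/m" for s in sensors]
    solve_count = 0
    if method == "reciprocal":
        op = ChargeOperator(head, config)
        for i, sensor in enumerate(sensors):
            try:
                matrix[i] = reciprocal_row(head, sensor, source_space, operator=op,
                                           cortical_surface=cortical_surface)
            except Exception as exc:
                raise RuntimeError(f"reciprocal row failed for sensor {sensor.name}") from exc
            solve_count += 1
            if progress:
                print(f"  row {i + 1}/{M} ({sensor.name})")
    elif method == "direct":
        op = ChargeOperator(head, config)
        for j in range(N):
            try:
                matrix[:, j] = direct_column(
                    head, source_space.positions[j], source_space.normals[j], sensors,
                    operator=op)
            except Exception as exc:
                raise RuntimeError(f"direct column failed for dipole {j}") from exc
            solve_count += 1
            if progress and (j + 1) % 50 == 0:
                print(f"  column {j + 1}/{N}")
    elif method == "analytic":
        center = np.zeros(3) if sphere_center is None else np.asarray(sphere_center)
        for i, sensor in enumerate(sensors):
            for j in range(N):
                B = sarvas_field(source_space.positions[j], source_space.normals[j],
                                 center, sensor.quad_points)
                matrix[i, j] = sensor_output_from_B(B, sensor)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Leadfield(matrix, sensors.names, source_space, method, units, solve_count)
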