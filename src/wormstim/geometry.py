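"""Parametric worm body, body-frame coordinates and kinematic posing.

The body is a tube of default length 1 mm and maximum radius 0.04 mm whose
surface ("cuticle") carries 330 mesh nodes grouped into 33 axial slices.
Body-relative coordinates are ``(u, phi, r_frac)``: axial position
``u in [0, 1]`` (0 = nose, 1 = tail), angular position ``phi`` in degrees on
the transversal plane (0 = dorsal midline, 90 = left, 180 = ventral,
270 = right) and radial position as a fraction of the local body radius.

Locomotion is an open-loop planar undulation: the centerline is a travelling
sinusoid around the heading axis.  This kinematics provider stands in for a
full soft-body simulation; it supplies exactly the quantities the stimulus
models consume (world positions, distances, slice membership, muscle
lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .registry import Registry

__all__ = [
    "BodyMesh",
    "Undulation",
    "KinematicState",
    "WormState",
    "build_body_mesh",
    "pose_points",
    "reference_points",
    "pose_worm",
]


@dataclass(frozen=True)
class BodyMesh:
    """Discretized cuticle surface of the parametric body tube."""

    length: float  # mm
    max_radius: float  # mm
    n_slices: int
    u: np.ndarray  # (n_nodes,) axial coordinate of each cuticle node
    phi: np.ndarray  # (n_nodes,) angular coordinate, degrees
    slice_index: np.ndarray  # (n_nodes,) int, slice containing the node

    @property
    def n_nodes(self) -> int:
        return self.u.size

    def radius(self, u) -> np.ndarray:
        """Local body radius (mm): elliptic profile, zero at both tips."""
        u = np.asarray(u, dtype=float)
        return self.max_radius * np.sqrt(np.clip(4.0 * u * (1.0 - u), 0.0, None))

    def slice_centers(self) -> np.ndarray:
        """Axial coordinates of the 33 slice centroids (the centerline u)."""
        return (np.arange(self.n_slices) + 0.5) / self.n_slices


@dataclass(frozen=True)
class Undulation:
    """Sinusoidal gait parameters of the open-loop kinematics provider."""

    amplitude: float = 0.1  # mm, lateral peak offset
    wavelength: float = 0.65  # mm, body wavelength of the travelling wave
    frequency: float = 0.3  # Hz, undulation frequency
    speed: float = 0.15  # mm/s, forward crawling speed

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("undulation amplitude must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("undulation wavelength must be > 0")


@dataclass(frozen=True)
class KinematicState:
    """World placement of the worm at one instant."""

    t: float  # s
    head_position: tuple[float, float]  # mm, on the plate plane
    heading: float  # radians, direction of travel in the plate plane
    undulation: Undulation = field(default_factory=Undulation)


def build_body_mesh(
    length_mm: float = 1.0,
    n_cuticle: int = 330,
    n_slices: int = 33,
    max_radius_mm: float = 0.04,
) -> BodyMesh:
    """Distribute ``n_cuticle`` surface nodes over ``n_slices`` axial rings.

    Nodes are placed ring-per-slice, each ring at its slice centroid, with
    ring populations as even as possible and ring angles evenly spaced.
    """
    if length_mm <= 0:
        raise ValueError("body length must be positive")
    if n_cuticle < 1 or n_slices < 1:
        raise ValueError("node and slice counts must be positive")
    base, rem = divmod(n_cuticle, n_slices)
    centers = (np.arange(n_slices) + 0.5) / n_slices
    u_list, phi_list, slc_list = [], [], []
    for i in range(n_slices):
        k = base + (1 if i < rem else 0)
        if k == 0:
            continue
        u_list.append(np.full(k, centers[i]))
        phi_list.append(np.arange(k) * (360.0 / k))
        slc_list.append(np.full(k, i, dtype=int))
    return BodyMesh(
        length=float(length_mm),
        max_radius=float(max_radius_mm),
        n_slices=int(n_slices),
        u=np.concatenate(u_list),
        phi=np.concatenate(phi_list),
        slice_index=np.concatenate(slc_list),
    )


def _centerline_xy(mesh: BodyMesh, kin: KinematicState, u: np.ndarray):
    """Centerline world positions and forward unit vectors at axial u."""
    und = kin.undulation
    fwd = np.array([np.cos(kin.heading), np.sin(kin.heading)])
    left = np.array([-fwd[1], fwd[0]])  # 90 deg counter-clockwise of forward
    head = np.asarray(kin.head_position, dtype=float)

    phase = 2.0 * np.pi * (u * mesh.length / und.wavelength - und.frequency * kin.t)
    lateral = und.amplitude * np.sin(phase)
    xy = head - np.outer(u * mesh.length, fwd) + np.outer(lateral, left)

    # analytic derivative w.r.t. u; forward tangent points nose-ward (-d/du)
    dlat = und.amplitude * np.cos(phase) * 2.0 * np.pi * mesh.length / und.wavelength
    d_xy = -mesh.length * fwd[None, :] + dlat[:, None] * left[None, :]
    tangent = -d_xy
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    return xy, tangent


def pose_points(
    mesh: BodyMesh,
    kin: KinematicState,
    u,
    phi_deg,
    r_frac,
) -> np.ndarray:
    """Map body-relative ``(u, phi, r_frac)`` points to world space (mm).

    The local transversal frame at axial position u is spanned by the plate
    normal (phi = 0, dorsal) and the in-plane left-of-heading direction
    (phi = 90); points are swept around the centerline with the local radius.
    Returns an (N, 3) array of ``(x, y, z)`` with z = 0 the plate plane
    through the centerline.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    phi = np.deg2rad(np.atleast_1d(np.asarray(phi_deg, dtype=float)))
    r = mesh.radius(u) * np.atleast_1d(np.asarray(r_frac, dtype=float))

    xy, tangent = _centerline_xy(mesh, kin, u)
    left_n = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)

    out = np.empty((u.size, 3))
    out[:, :2] = xy + (r * np.sin(phi))[:, None] * left_n
    out[:, 2] = r * np.cos(phi)
    return out


_REFERENCE_UNDULATION = Undulation(amplitude=0.0, wavelength=1.0, frequency=0.0, speed=0.0)


def reference_state(t: float = 0.0) -> KinematicState:
    """Straight reference pose: nose at the origin, heading along +x."""
    return KinematicState(
        t=t, head_position=(0.0, 0.0), heading=0.0, undulation=_REFERENCE_UNDULATION
    )


def reference_points(mesh: BodyMesh, u, phi_deg, r_frac) -> np.ndarray:
    """Body-frame world coordinates of points on the straight reference pose."""
    return pose_points(mesh, reference_state(), u, phi_deg, r_frac)


@dataclass
class WormState:
    """Time-stamped world-space body: centerline, cuticle, neurons, muscles."""

    t: float
    kin: KinematicState
    mesh: BodyMesh
    centerline: np.ndarray  # (n_slices, 3)
    centerline_u: np.ndarray  # (n_slices,)
    cuticle_world: np.ndarray  # (n_nodes, 3)
    neuron_world: dict[str, np.ndarray]  # name -> (k, 3); row 0 is the soma
    sensilla_world: dict[str, np.ndarray]  # name -> (3,)
    arbor_world: dict[str, np.ndarray]  # name -> (m, 3) dendritic arbor points
    axon_world: dict[str, np.ndarray]  # name -> (m, 3) elongated axon points
    muscle_lengths: dict[str, float]  # name -> current polyline length, mm


def _registry_point_cloud(registry: "Registry"):
    """Concatenated body-relative points of everything that must be posed.

    Cached on the registry instance so repeated posing is a single
    vectorized transform per timestep.
    """
    cache = getattr(registry, "_pose_cache", None)
    if cache is not None:
        return cache
    us, phis, rs = [], [], []
    spans: list[tuple[str, str, int, int]] = []  # (kind, name, start, stop)
    cursor = 0

    def push(kind: str, name: str, pts: np.ndarray) -> None:
        nonlocal cursor
        us.append(pts[:, 0])
        phis.append(pts[:, 1])
        rs.append(pts[:, 2])
        spans.append((kind, name, cursor, cursor + len(pts)))
        cursor += len(pts)

    for name, rec in registry.neurons.items():
        pts = np.vstack([
            np.array([[rec.u_soma, rec.phi_soma, rec.r_frac]]),
            np.asarray(rec.process, dtype=float).reshape(-1, 3),
        ])
        push("neuron", name, pts)
    for name, sens in registry.sensilla.items():
        push("sensillum", name, np.array([[sens.u, sens.phi, sens.r_frac]]))
    for name, pts in registry.arbors.items():
        push("arbor", name, pts)
    for name, pts in registry.axons.items():
        push("axon", name, pts)
    for name, mus in registry.muscles.items():
        push("muscle", name, mus.nodes)

    cache = (
        np.concatenate(us),
        np.concatenate(phis),
        np.concatenate(rs),
        spans,
    )
    registry._pose_cache = cache
    return cache


def pose_worm(mesh: BodyMesh, registry: "Registry", kin: KinematicState) -> WormState:
    """Pose the full body in world space from one kinematic state."""
    cl_u = mesh.slice_centers()
    cl_xy, _ = _centerline_xy(mesh, kin, cl_u)
    centerline = np.column_stack([cl_xy, np.zeros(cl_u.size)])

    cuticle = pose_points(mesh, kin, mesh.u, mesh.phi, np.ones(mesh.n_nodes))

    u, phi, r, spans = _registry_point_cloud(registry)
    world = pose_points(mesh, kin, u, phi, r)

    neuron_world: dict[str, np.ndarray] = {}
    sensilla_world: dict[str, np.ndarray] = {}
    arbor_world: dict[str, np.ndarray] = {}
    axon_world: dict[str, np.ndarray] = {}
    muscle_lengths: dict[str, float] = {}
    for kind, name, a, b in spans:
        pts = world[a:b]
        if kind == "neuron":
            neuron_world[name] = pts
        elif kind == "sensillum":
            sensilla_world[name] = pts[0]
        elif kind == "arbor":
            arbor_world[name] = pts
        elif kind == "axon":
            axon_world[name] = pts
        else:  # muscle
            muscle_lengths[name] = float(
                np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
            )

    return WormState(
        t=kin.t,
        kin=kin,
        mesh=mesh,
        centerline=centerline,
        centerline_u=cl_u,
        cuticle_world=cuticle,
        neuron_world=neuron_world,
        sensilla_world=sensilla_world,
        arbor_world=arbor_world,
        axon_world=axon_world,
        muscle_lengths=muscle_lengths,
    )
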