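"""Chemosensation: plate concentration fields and sensilla routing.

Static assay layouts (four-quadrant plates with barrier strips, osmotic
rings, steady point sources) do not diffuse during the assay.  The steady
point source is a Gaussian gradient

    c(x, y) = c0 * exp(-((x - x0)^2 + (y - y0)^2) / (2 lambda_c^2)),

with peak concentration ``c0`` (mM) and decay length ``lambda_c`` (mm).

The dynamic drop test follows the 2-D diffusion equation
``dC/dt = D laplacian(C)``, solved by Gaussian blurring: one step of length
``dt`` convolves the field with an isotropic Gaussian kernel of variance
``2 D dt`` (reflective plate boundary, so total mass is conserved).  Because
blurs compose (variances add), a Gaussian initial blob of width ``sigma0``
admits the closed form

    c(r, t) = c0 * sigma0^2 / (sigma0^2 + 2 D t) * exp(-r^2 / (2 (sigma0^2 + 2 D t))),

which ``drop_concentration`` evaluates directly; the grid and the closed
form agree to discretization error and are cross-checked in the tests.

Delivery: each sensillum samples the field at its posed world position
(projected onto the plate plane) and every member neuron receives that
value; a neuron belonging to several sensilla receives the maximum.  All
sensilla classes (amphids, phasmids, labial, cephalic, deirid) participate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import WormState
from .registry import Registry

__all__ = [
    "SUBSTANCE_ROLES",
    "QuadrantField",
    "RingField",
    "PointSourceField",
    "DropField",
    "init_drop",
    "diffuse",
    "drop_concentration",
    "eval_static_field",
    "chemo_stimuli",
]

SUBSTANCE_ROLES = {
    "NaCl": "attractant",
    "biotin": "attractant",
    "ethanol": "attractant",
    "butanone": "attractant",
    "CuSO4": "barrier",
    "SDS": "barrier",
    "quinine": "repellent",
    "benzaldehyde": "repellent",
    "diacetyl": "repellent",
    "sodium_azide": "immobilizer",
}


@dataclass(frozen=True)
class QuadrantField:
    """Four-substance plate with a cross-shaped barrier strip on the axes.

    Quadrants are numbered counter-clockwise from the (+x, +y) quadrant.
    Points inside the barrier strip (and exactly on a quadrant boundary)
    carry the barrier substance.
    """

    quadrants: tuple[tuple[str, float], ...]  # 4 x (substance, mM)
    barrier: tuple[str, float]  # (substance, mM)
    barrier_width: float = 2.0  # mm
    center: tuple[float, float] = (0.0, 0.0)
    plate_diameter: float = 50.0  # mm

    def __post_init__(self) -> None:
        if len(self.quadrants) != 4:
            raise ValueError("quadrant layout needs exactly 4 quadrants")
        for _, conc in (*self.quadrants, self.barrier):
            if conc < 0:
                raise ValueError("concentrations must be >= 0")

    @property
    def substances(self) -> list[str]:
        names = [s for s, _ in self.quadrants] + [self.barrier[0]]
        return sorted(set(names))


@dataclass(frozen=True)
class RingField:
    """Annular chemical barrier (osmotic ring) centered on the plate."""

    substance: str
    concentration: float  # mM
    r_inner: float  # mm
    r_outer: float  # mm
    center: tuple[float, float] = (0.0, 0.0)
    plate_diameter: float = 50.0

    def __post_init__(self) -> None:
        if not (0 <= self.r_inner < self.r_outer):
            raise ValueError("ring radii must satisfy 0 <= inner < outer")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    @property
    def substances(self) -> list[str]:
        return [self.substance]


@dataclass(frozen=True)
class PointSourceField:
    """Steady Gaussian gradient around a static point source."""

    substance: str
    c0: float  # mM, peak concentration at the source
    lambda_c: float  # mm, decay length
    center: tuple[float, float] = (0.0, 0.0)
    plate_diameter: float = 50.0

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        if self.lambda_c <= 0:
            raise ValueError("lambda_c must be > 0")

    @property
    def substances(self) -> list[str]:
        return [self.substance]


def eval_static_field(spec, points) -> dict[str, np.ndarray]:
    """Concentration of each substance (mM) at the given plate points.

    ``points`` is (N, 2) or (N, 3); only the plate-plane projection is used.
    Points outside the plate read zero for every substance.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    cx, cy = spec.center
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    # plate membership uses the plate center at the origin of the layout
    on_plate = dx**2 + dy**2 <= (spec.plate_diameter / 2.0) ** 2
    out = {s: np.zeros(len(pts)) for s in spec.substances}

    if isinstance(spec, PointSourceField):
        c = spec.c0 * np.exp(-(dx**2 + dy**2) / (2.0 * spec.lambda_c**2))
        out[spec.substance] = np.where(on_plate, c, 0.0)
        return out

    if isinstance(spec, RingField):
        r = np.hypot(dx, dy)
        inside = (r >= spec.r_inner) & (r <= spec.r_outer) & on_plate
        out[spec.substance] = np.where(inside, spec.concentration, 0.0)
        return out

    if isinstance(spec, QuadrantField):
        half = spec.barrier_width / 2.0
        in_barrier = (np.abs(dx) <= half) | (np.abs(dy) <= half)
        bsub, bconc = spec.barrier
        out[bsub] = np.where(in_barrier & on_plate, bconc,
                             out.get(bsub, np.zeros(len(pts))))
        quadrant_masks = [
            (dx > half) & (dy > half),
            (dx < -half) & (dy > half),
            (dx < -half) & (dy < -half),
            (dx > half) & (dy < -half),
        ]
        for (sub, conc), mask in zip(spec.quadrants, quadrant_masks):
            out[sub] = np.where(mask & on_plate, conc, out[sub])
        return out

    raise TypeError(f"unknown static field spec {type(spec).__name__}")


@dataclass
class DropField:
    """Diffusing chemical drop on a regular 2-D lattice over the plate."""

    substance: str
    C: np.ndarray  # (ny, nx) concentration, mM
    spacing: float  # mm
    origin: tuple[float, float]  # world coords of cell (0, 0)
    D: float  # mm^2/s
    t: float = 0.0  # s since drop delivery
    sigma0: float = 0.0  # mm, width of the initial Gaussian blob

    @property
    def total_mass(self) -> float:
        """Integrated concentration, mM * mm^2 (conserved by diffusion)."""
        return float(self.C.sum() * self.spacing**2)


def init_drop(
    center: tuple[float, float],
    c0: float,
    radius: float,
    spacing: float = 0.05,
    plate_diameter: float = 50.0,
    D: float = 1e-4,
    substance: str = "custom",
) -> DropField:
    """Deliver a drop as a Gaussian blob of peak ``c0`` (mM) and width
    ``radius`` (mm, one standard deviation) centered at ``center``."""
    if c0 < 0 or radius <= 0 or spacing <= 0 or D <= 0:
        raise ValueError("drop parameters must be positive (c0 >= 0)")
    half = plate_diameter / 2.0
    n = int(round(plate_diameter / spacing)) + 1
    xs = -half + spacing * np.arange(n)
    ys = -half + spacing * np.arange(n)
    gx = np.exp(-0.5 * ((xs - center[0]) / radius) ** 2)
    gy = np.exp(-0.5 * ((ys - center[1]) / radius) ** 2)
    C = c0 * gy[:, None] * gx[None, :]
    return DropField(
        substance=substance, C=C, spacing=spacing,
        origin=(-half, -half), D=D, t=0.0, sigma0=radius,
    )


def diffuse(drop: DropField, dt: float) -> DropField:
    """Advance the drop by ``dt`` seconds: Gaussian blur of variance 2*D*dt.

    The plate edge is reflective (no-flux), so total mass is conserved.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sigma_mm = np.sqrt(2.0 * drop.D * dt)
    if sigma_mm < drop.spacing:
        warnings.warn(
            "diffusion kernel narrower than the grid spacing; the blur is "
            "undersampled", stacklevel=2)
    C = ndimage.gaussian_filter(
        drop.C, sigma=sigma_mm / drop.spacing, mode="reflect")
    return DropField(
        substance=drop.substance, C=C, spacing=drop.spacing,
        origin=drop.origin, D=drop.D, t=drop.t + dt, sigma0=drop.sigma0,
    )


def sample_drop(drop: DropField, points) -> np.ndarray:
    """Bilinear sample of the drop grid at plate points (N, 2) or (N, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    cols = (pts[:, 0] - drop.origin[0]) / drop.spacing
    rows = (pts[:, 1] - drop.origin[1]) / drop.spacing
    return ndimage.map_coordinates(
        drop.C, np.vstack([rows, cols]), order=1, mode="nearest")


def drop_concentration(
    center: tuple[float, float],
    c0: float,
    radius: float,
    D: float,
    t: float,
    points,
) -> np.ndarray:
    """Closed-form concentration of a Gaussian drop after ``t`` seconds.

    Equivalent to grid diffusion far from the plate boundary; used by the
    experiment engine so that per-timestep sampling needs no grid stepping.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    var = radius**2 + 2.0 * D * max(t, 0.0)
    r2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return c0 * (radius**2 / var) * np.exp(-r2 / (2.0 * var))


def chemo_stimuli(
    fields: list,
    worm_state: WormState,
    registry: Registry,
    t: float | None = None,
) -> dict[tuple[str, str], float]:
    """Route plate concentrations to neurons through their sensilla.

    ``fields`` may mix static layouts and ``(DropField | callable)`` entries;
    a callable must map an (N, 2) point array to concentrations and expose a
    ``substance`` attribute.  Returns ``(neuron, substance) -> mM``.
    """
    names = list(registry.sensilla)
    pts = np.vstack([worm_state.sensilla_world[n][:2] for n in names])

    per_sensillum: dict[str, dict[str, float]] = {n: {} for n in names}
    for spec in fields:
        if isinstance(spec, DropField):
            values = {spec.substance: sample_drop(spec, pts)}
        elif callable(spec):
            values = {spec.substance: np.asarray(spec(pts), dtype=float)}
        else:
            values = eval_static_field(spec, pts)
        for sub, arr in values.items():
            for i, n in enumerate(names):
                prev = per_sensillum[n].get(sub, 0.0)
                per_sensillum[n][sub] = prev + float(arr[i])

    stimuli: dict[tuple[str, str], float] = {}
    for sname, sens in registry.sensilla.items():
        for sub, value in per_sensillum[sname].items():
            for neuron in sens.members:
                key = (neuron, sub)
                stimuli[key] = max(stimuli.get(key, 0.0), value)
    return stimuli
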