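"""Mechanosensation: touch, collision and plate-tap stimuli.

A localized surface force of amplitude ``F_p`` (uN) applied at point ``p`` is
first spread over the cuticle mesh nodes with a Gaussian spatial weight,

    F_c = sum_p F_p * Gauss(d(p, c)),    Gauss(x) = exp(-x^2 / 2 sigma^2) / (sigma sqrt(2 pi)),

with weights below ``cutoff`` (relative to Gauss(0)) zeroed.  Each loaded
node then stimulates every mechanosensory neuron through the inverse of the
distance between the node and the nearest point of the neuron's discretized
soma-plus-process geometry,

    Stimuli_N = sum_c F_c / d(n_c, c),   n_c = argmin_{i in N} d(i, c),

summed over the loaded cuticle nodes.  Stimulus units are uN/mm and are not
renormalized; interpretation is left to downstream neuron models.

To keep the propagation local (and mirror the thresholding applied to the
Gaussian spreading), node->neuron weights are zeroed beyond a cutoff radius
``max_range`` defaulting to ``sigma * sqrt(2 ln(1/cutoff))`` — the distance at
which the spreading Gaussian itself falls below the cutoff.  Passing
``max_range=None`` restores pure inverse-distance propagation.

Plate-tap is non-localized: a bell-shaped force profile is delivered
identically to every mechanosensory neuron, bypassing the spatial pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import WormState
from .registry import Registry

__all__ = [
    "TouchEvent",
    "force_profile",
    "resolve_application_point",
    "distribute_surface_force",
    "propagate_to_neurons",
    "touch_stimuli",
    "plate_tap_profile",
    "plate_tap_stimuli",
    "collision_stimulus",
    "default_max_range",
]

DEFAULT_SIGMA = 0.05  # mm, Gaussian spread of the surface force
DEFAULT_CUTOFF = 1e-3  # relative weight below which Gaussian terms are zeroed
DEFAULT_EPSILON = 1e-4  # mm, floor on node-neuron distance in the 1/d weight

GENTLE_AMPLITUDE = 10.0  # uN
HARSH_AMPLITUDE = 100.0  # uN


@dataclass(frozen=True)
class TouchEvent:
    """One scheduled touch-family stimulus event."""

    kind: str  # gentle | harsh | collision | plate_tap
    amplitude: float  # uN
    onset: float  # s
    duration: float  # s
    point: tuple[float, float] | tuple[float, float, float] | None = None
    body_relative: bool = True  # point is (u, phi) if True, world (x,y,z) if not
    ramp: tuple[float, float, float] | None = None  # (rise, hold, fall), s
    sigma: float = DEFAULT_SIGMA
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.kind not in {"gentle", "harsh", "collision", "plate_tap"}:
            raise ValueError(f"unknown touch kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("touch amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("touch duration must be > 0")
        if self.sigma <= 0:
            raise ValueError("touch sigma must be > 0")

    def ramp_times(self) -> tuple[float, float, float]:
        """(rise, hold, fall) in seconds; defaults depend on the touch kind:
        soft ramps (duration/4) for gentle touch, steep ones (duration/20)
        for harsh touch."""
        if self.ramp is not None:
            return self.ramp
        frac = 0.25 if self.kind == "gentle" else 0.05
        rise = fall = self.duration * frac
        return rise, self.duration - rise - fall, fall


def force_profile(event: TouchEvent, t) -> np.ndarray:
    """Instantaneous force amplitude F_p(t) in uN.

    Gentle/harsh/collision touches use a trapezoid (linear rise, hold,
    linear fall); plate-tap uses a Gaussian bell peaking at the configured
    amplitude mid-event.
    """
    t = np.asarray(t, dtype=float)
    tau = t - event.onset
    if event.kind == "plate_tap":
        mid = event.duration / 2.0
        width = event.duration / 6.0  # +-3 widths span the event window
        out = event.amplitude * np.exp(-0.5 * ((tau - mid) / width) ** 2)
        return np.where((tau >= 0) & (tau <= event.duration), out, 0.0)
    rise, hold, fall = event.ramp_times()
    out = np.zeros_like(tau)
    if rise > 0:
        out = np.where((tau >= 0) & (tau < rise), event.amplitude * tau / rise, out)
    on_hold = (tau >= rise) & (tau <= rise + hold)
    out = np.where(on_hold, event.amplitude, out)
    if fall > 0:
        falling = (tau > rise + hold) & (tau <= rise + hold + fall)
        out = np.where(
            falling, event.amplitude * (rise + hold + fall - tau) / fall, out)
    return out


def gauss(x, sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian weight used for the surface force spread."""
    x = np.asarray(x, dtype=float)
    return np.exp(-0.5 * (x / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))


def default_max_range(sigma: float, cutoff: float) -> float:
    """Propagation cutoff radius: where Gauss(d)/Gauss(0) drops to ``cutoff``."""
    return sigma * math.sqrt(2.0 * math.log(1.0 / cutoff))


def resolve_application_point(event: TouchEvent, worm_state: WormState) -> np.ndarray:
    """World coordinates of the touch application point on the cuticle."""
    if event.point is None:
        raise ValueError(f"{event.kind} event has no application point")
    if event.body_relative:
        u, phi = event.point[:2]
        from .geometry import pose_points

        return pose_points(worm_state.mesh, worm_state.kin, [u], [phi], [1.0])[0]
    pt = np.asarray(event.point, dtype=float)
    if pt.size == 2:
        pt = np.append(pt, 0.0)
    return pt


def distribute_surface_force(
    f_p: float,
    point: np.ndarray,
    worm_state: WormState,
    sigma: float = DEFAULT_SIGMA,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Spread a point force over the cuticle nodes (one value per node, uN).

    Weights with ``Gauss(d)/Gauss(0) < cutoff`` are zeroed.  Contributions of
    multiple simultaneous events simply add (the map is linear in ``f_p``).
    """
    point = np.asarray(point, dtype=float)
    d = np.linalg.norm(worm_state.cuticle_world - point[None, :], axis=1)
    if np.min(d) > 3.0 * sigma:
        warnings.warn(
            "touch point is farther than 3 sigma from every cuticle node; "
            "no force distributed", stacklevel=2)
        return np.zeros(worm_state.cuticle_world.shape[0])
    w = gauss(d, sigma)
    w[w / gauss(0.0, sigma) < cutoff] = 0.0
    return f_p * w


_MISSING = object()


def propagate_to_neurons(
    force_map: np.ndarray,
    worm_state: WormState,
    registry: Registry,
    epsilon: float = DEFAULT_EPSILON,
    max_range: float | None = _MISSING,  # type: ignore[assignment]
    sigma: float = DEFAULT_SIGMA,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, float]:
    """Inverse-distance propagation of cuticle forces to mechanosensory
    neurons.

    For each loaded node the nearest point of the neuron's discretized
    soma+process geometry is found and the node's force contributes
    ``F_c / max(d, epsilon)``, provided d does not exceed ``max_range``.
    """
    if max_range is _MISSING:
        max_range = default_max_range(sigma, cutoff)
    loaded = np.nonzero(force_map > 0)[0]
    stimuli: dict[str, float] = {}
    if loaded.size == 0:
        return {n: 0.0 for n in registry.neurons_with_modality("mechano")}
    nodes = worm_state.cuticle_world[loaded]
    forces = force_map[loaded]
    for name in registry.neurons_with_modality("mechano"):
        geom = worm_state.neuron_world.get(name)
        if geom is None or geom.size == 0:
            warnings.warn(f"neuron {name!r} has no geometry; excluded",
                          stacklevel=2)
            continue
        d = cdist(nodes, geom).min(axis=1)
        w = 1.0 / np.maximum(d, epsilon)
        if max_range is not None:
            w[d > max_range] = 0.0
        stimuli[name] = float(np.dot(forces, w))
    return stimuli


def touch_stimuli(
    event: TouchEvent,
    worm_state: WormState,
    registry: Registry,
    t,
    epsilon: float = DEFAULT_EPSILON,
    max_range: float | None = _MISSING,  # type: ignore[assignment]
) -> dict[str, np.ndarray]:
    """Full Eq.-style pipeline for one touch event at time(s) ``t``.

    Exploits linearity: the spatial weights are evaluated once for a unit
    force and scaled by the temporal profile.
    """
    point = resolve_application_point(event, worm_state)
    unit_map = distribute_surface_force(
        1.0, point, worm_state, event.sigma, event.cutoff)
    unit = propagate_to_neurons(
        unit_map, worm_state, registry, epsilon, max_range,
        sigma=event.sigma, cutoff=event.cutoff)
    profile = force_profile(event, t)
    return {name: w * profile for name, w in unit.items()}


def plate_tap_profile(amplitude: float, duration: float, onset: float, t) -> np.ndarray:
    """Bell-shaped tap profile shared by all mechanosensory neurons."""
    event = TouchEvent(kind="plate_tap", amplitude=amplitude,
                       onset=onset, duration=duration)
    return force_profile(event, t)


def plate_tap_stimuli(
    amplitude: float,
    duration: float,
    registry: Registry,
    t,
    onset: float = 0.0,
) -> dict[str, np.ndarray]:
    """Non-localized tap: identical bell profile to every mechanosensory
    neuron; neurons without the mechano flag receive nothing."""
    if amplitude < 0:
        raise ValueError("plate-tap amplitude must be >= 0")
    profile = plate_tap_profile(amplitude, duration, onset, t)
    return {name: profile.copy()
            for name in registry.neurons_with_modality("mechano")}


def collision_stimulus(
    contact_point: np.ndarray,
    contact_force: float,
    worm_state: WormState,
    registry: Registry,
    sigma: float = DEFAULT_SIGMA,
    cutoff: float = DEFAULT_CUTOFF,
    epsilon: float = DEFAULT_EPSILON,
    max_range: float | None = _MISSING,  # type: ignore[assignment]
) -> dict[str, float]:
    """Collision with an obstacle: identical pipeline to a touch event with
    the contact point and force supplied by the obstacle checker."""
    if contact_force == 0:
        return {}
    force_map = distribute_surface_force(
        contact_force, contact_point, worm_state, sigma, cutoff)
    return propagate_to_neurons(
        force_map, worm_state, registry, epsilon, max_range,
        sigma=sigma, cutoff=cutoff)
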