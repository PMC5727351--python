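"""Thermosensation: global temperature profile and spatial gradients.

Three assay modes are modeled.  A *global change* ramps the plate-wide
temperature linearly from a start to an end value over the event window and
holds the end value afterwards; it is independent of the worm's position.
A *linear gradient* interpolates temperature affinely across the plate along
a fixed axis, and a *heat point* is a steady circular gradient

    T(r) = base + (T_peak - base) * exp(-r^2 / (2 decay^2))

around a heated spot.  Spatial fields are steady-state and not updated in
time.

Delivery: a thermosensory neuron samples the field at its sensillum position
when it belongs to one, else at its soma.  The intensively branched PVD and
FLP neurons report the *minimum* and *maximum* temperature sensed anywhere
along their dendritic arbor, respectively (PVD responds to acute cold shock,
FLP to noxious heat).  The worm's body does not insulate or transport heat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WormState
from .registry import Registry

__all__ = [
    "GlobalTemperature",
    "LinearGradient",
    "HeatPoint",
    "global_temperature",
    "eval_thermal_field",
    "thermo_stimuli",
]

DEFAULT_BASE_C = 20.0


@dataclass(frozen=True)
class GlobalTemperature:
    """Plate-wide temperature ramp in time."""

    base: float = DEFAULT_BASE_C  # deg C before the event
    start: float = 15.0  # deg C at onset
    end: float = 25.0  # deg C at onset + duration (held afterwards)
    onset: float = 0.0  # s
    duration: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class LinearGradient:
    """Steady left-to-right affine temperature profile across the plate."""

    t_left: float  # deg C at x = -plate_diameter/2 along the axis
    t_right: float  # deg C at x = +plate_diameter/2
    axis: tuple[float, float] = (1.0, 0.0)  # gradient direction in the plane
    plate_diameter: float = 50.0  # mm


@dataclass(frozen=True)
class HeatPoint:
    """Steady circular gradient around a locally heated spot."""

    peak: float  # deg C at the center
    center: tuple[float, float]  # mm
    decay: float  # mm, Gaussian decay length
    base: float = DEFAULT_BASE_C  # deg C far from the spot

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError("decay length must be > 0")


def global_temperature(spec: GlobalTemperature, t) -> np.ndarray:
    """Temperature (deg C) at time(s) t: base before onset, linear ramp
    start->end over the duration, end value held afterwards."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - spec.onset) / spec.duration, 0.0, 1.0)
    ramp = spec.start + (spec.end - spec.start) * frac
    return np.where(t < spec.onset, spec.base, ramp)


def eval_thermal_field(spec, points) -> np.ndarray:
    """Temperature (deg C) of a spatial field at plate points (N, 2|3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    if isinstance(spec, LinearGradient):
        axis = np.asarray(spec.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        s = pts @ axis  # signed coordinate along the gradient axis
        half = spec.plate_diameter / 2.0
        frac = (s + half) / spec.plate_diameter
        return spec.t_left + (spec.t_right - spec.t_left) * frac
    if isinstance(spec, HeatPoint):
        r2 = ((pts - np.asarray(spec.center)) ** 2).sum(axis=1)
        return spec.base + (spec.peak - spec.base) * np.exp(
            -r2 / (2.0 * spec.decay**2))
    raise TypeError(f"unknown thermal field spec {type(spec).__name__}")


def _sensing_point(name: str, registry: Registry, worm_state: WormState) -> np.ndarray:
    rec = registry.neurons[name]
    if rec.sensilla:
        sname = sorted(rec.sensilla)[0]
        return worm_state.sensilla_world[sname]
    return worm_state.neuron_world[name][0]


def thermo_stimuli(
    spec,
    worm_state: WormState,
    registry: Registry,
    t: float = 0.0,
) -> dict[str, float]:
    """Per-neuron temperature stimulus (deg C) for one field or ramp.

    Point-rule neurons sample at their sensillum (if any) or soma; arbor-rule
    neurons report the min (PVD) or max (FLP) over their discretized arbor.
    A global ramp reaches every thermosensory neuron identically.
    """
    names = registry.neurons_with_modality("thermo")
    if isinstance(spec, GlobalTemperature):
        value = float(global_temperature(spec, t))
        return {n: value for n in names}

    stimuli: dict[str, float] = {}
    for name in names:
        rule = registry.neurons[name].arbor_rule
        if rule != "point" and name in worm_state.arbor_world:
            temps = eval_thermal_field(spec, worm_state.arbor_world[name])
            value = float(temps.min() if rule == "min_over_arbor" else temps.max())
        else:
            value = float(eval_thermal_field(
                spec, _sensing_point(name, registry, worm_state)[None, :])[0])
        stimuli[name] = value
    return stimuli
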