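"""Galvanosensation pulse trains and photosensation light beams.

Electric shocks are box-function pulse trains (amplitude in nA, pulse
repetition frequency, pulse duration) delivered identically to *all* neurons
regardless of position — directed charge to a specific neuron is not
achievable in the plate assay.  Light pulses are a circular beam of constant
intensity (a single temporal box, not a train): every neuron whose soma lies
inside the beam radius on the plate plane receives the configured intensity
for the pulse duration; the body does not absorb or attenuate the light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WormState
from .registry import Registry

__all__ = [
    "ElectricShockSpec",
    "LightPulseSpec",
    "electric_pulse_train",
    "light_stimuli",
    "beam_members",
]


@dataclass(frozen=True)
class ElectricShockSpec:
    """Box-function pulse train applied to the whole body."""

    amplitude: float  # nA
    frequency: float  # Hz, pulse repetition rate
    pulse_duration: float  # s, width of each pulse
    onset: float = 0.0  # s
    train_duration: float = 1.0  # s, total window of the train

    def __post_init__(self) -> None:
        if min(self.amplitude, self.frequency, self.pulse_duration,
               self.train_duration) <= 0:
            raise ValueError("shock parameters must be positive")
        if self.pulse_duration > 1.0 / self.frequency:
            raise ValueError(
                "pulse_duration must not exceed the pulse period 1/frequency")


@dataclass(frozen=True)
class LightPulseSpec:
    """Circular constant-intensity beam (laser-pointer illumination)."""

    intensity: float  # arbitrary amplitude
    radius: float = 0.2  # mm
    onset: float = 0.0  # s
    duration: float = 0.190  # s
    center: tuple[float, float] | None = None  # world (x, y), mm
    center_u: float | None = None  # or body-relative axial position
    wavelength: float | None = None  # nm, metadata only

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.duration <= 0:
            raise ValueError("beam radius and duration must be > 0")
        if (self.center is None) == (self.center_u is None):
            raise ValueError("specify exactly one of center / center_u")


def electric_pulse_train(spec: ElectricShockSpec, t) -> np.ndarray:
    """Train value (nA) at time(s) t: ``amplitude`` while the phase within
    each period is inside the pulse and t is inside the train window."""
    t = np.asarray(t, dtype=float)
    tau = t - spec.onset
    period = 1.0 / spec.frequency
    in_train = (tau >= 0) & (tau < spec.train_duration)
    in_pulse = np.mod(tau, period) < spec.pulse_duration
    return np.where(in_train & in_pulse, spec.amplitude, 0.0)


def _beam_center(spec: LightPulseSpec, worm_state: WormState) -> np.ndarray:
    if spec.center is not None:
        return np.asarray(spec.center, dtype=float)
    from .geometry import pose_points

    pt = pose_points(worm_state.mesh, worm_state.kin, [spec.center_u], [0.0], [0.0])
    return pt[0, :2]


def beam_members(spec: LightPulseSpec, worm_state: WormState,
                 registry: Registry) -> list[str]:
    """Neurons whose soma lies within the beam (plate-plane distance
    ``<= radius``, boundary inclusive)."""
    center = _beam_center(spec, worm_state)
    members = []
    for name in registry.neurons_with_modality("photo"):
        soma = worm_state.neuron_world[name][0, :2]
        if np.hypot(*(soma - center)) <= spec.radius:
            members.append(name)
    return members


def light_stimuli(
    spec: LightPulseSpec,
    worm_state: WormState,
    registry: Registry,
    t,
) -> dict[str, np.ndarray]:
    """Per-neuron beam intensity at time(s) t.

    Neurons inside the beam receive ``intensity`` for
    ``onset <= t < onset + duration``; everyone else reads zero.
    """
    t = np.asarray(t, dtype=float)
    window = ((t >= spec.onset) & (t < spec.onset + spec.duration)).astype(float)
    inside = set(beam_members(spec, worm_state, registry))
    return {
        name: spec.intensity * window if name in inside else np.zeros_like(window)
        for name in registry.neurons_with_modality("photo")
    }
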