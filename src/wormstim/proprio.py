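"""Proprioception: centerline curvature and muscle-stretch self-sensing.

Curvature is measured at the 33 centerline points (slice centroids),
restricted to the plate plane.  At each interior point the signed
circumcircle (Menger) curvature of the point and its two neighbors is used;
the sign is positive when the body bends toward the right of the direction
of travel (the ventral side under this package's conventions) and the two
endpoints copy their interior neighbor.  Each curvature-sensing neuron reads
the value at the centerline point nearest its soma; neurons with extended
geometry (touch-receptor processes, elongated A/B motor axons) average the
values at the points nearest each of their geometry samples, i.e. the summed
response is normalized by the number of sensing segments.

Muscle stretch is the dimensionless strain (length - rest) / rest of each
muscle, routed directly to the motor neurons that synapse onto it: a
neuron's stimulus is the connection-weighted mean strain over its muscles.
No head-to-tail efficacy gradient is applied; such compensation is left to
the sensitivity of the downstream neuron models.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import WormState
from .registry import Registry

__all__ = [
    "centerline_curvature",
    "curvature_stimuli",
    "muscle_stretch_stimuli",
]


def centerline_curvature(centerline: np.ndarray) -> np.ndarray:
    """Signed planar curvature (1/mm) at every centerline point.

    ``centerline`` is (n, 2|3) ordered nose to tail; only the plate-plane
    projection enters.  Interior points get the signed circumcircle curvature
    of their 3-point neighborhood; endpoints replicate their neighbor.
    Degenerate neighborhoods (duplicate consecutive points) yield 0 with a
    warning.
    """
    pts = np.asarray(centerline, dtype=float)[:, :2]
    n = len(pts)
    if n < 3:
        raise ValueError("curvature needs at least 3 centerline points")
    kappa = np.zeros(n)
    v1 = pts[1:-1] - pts[:-2]
    v2 = pts[2:] - pts[1:-1]
    chord = pts[2:] - pts[:-2]
    a = np.linalg.norm(v1, axis=1)
    b = np.linalg.norm(v2, axis=1)
    c = np.linalg.norm(chord, axis=1)
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    denom = a * b * c
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            "duplicate consecutive centerline points; curvature set to 0",
            stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        interior = np.where(degenerate, 0.0, 2.0 * cross / denom)
    # walking nose->tail, a positive cross product bends the body toward the
    # right of the direction of travel: the ventral-positive convention
    kappa[1:-1] = interior
    kappa[0] = kappa[1]
    kappa[-1] = kappa[-2]
    return kappa


def _geometry_points(name: str, worm_state: WormState) -> np.ndarray:
    """Curvature-sensing sample points: soma + process, plus axon span."""
    parts = [worm_state.neuron_world[name]]
    axon = worm_state.axon_world.get(name)
    if axon is not None:
        parts.append(axon)
    return np.vstack(parts)


def curvature_stimuli(
    kappa: np.ndarray,
    registry: Registry,
    worm_state: WormState,
) -> dict[str, float]:
    """Route curvature samples to the curvature-sensing neurons (1/mm).

    Point neurons read the sample nearest their soma; multi-point neurons
    read the mean over the samples nearest each geometry point.
    """
    centers = worm_state.centerline[:, :2]
    stimuli: dict[str, float] = {}
    for name in registry.neurons_with_modality("proprio_curvature"):
        geom = _geometry_points(name, worm_state)[:, :2]
        nearest = cdist(geom, centers).argmin(axis=1)
        stimuli[name] = float(kappa[nearest].mean())
    return stimuli


def muscle_stretch_stimuli(
    worm_state: WormState,
    registry: Registry,
) -> dict[str, float]:
    """Connection-weighted mean muscle strain per motor neuron.

    Strain of muscle m is ``(length_m - rest_m) / rest_m``; a neuron's
    stimulus is ``sum_m w(N, m) s_m / sum_m w(N, m)`` over its connected
    muscles.  Neurons with zero total weight are excluded.
    """
    strains = {
        name: (worm_state.muscle_lengths[name] - rec.rest_length) / rec.rest_length
        for name, rec in registry.muscles.items()
    }
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for row in registry.connectivity.itertuples(index=False):
        w = float(row.weight)
        num[row.neuron] = num.get(row.neuron, 0.0) + w * strains[row.muscle]
        den[row.neuron] = den.get(row.neuron, 0.0) + w
    return {n: num[n] / den[n] for n in num if den[n] > 0}
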