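"""Touch force profiles, Gaussian spreading and inverse-distance propagation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from wormstim import TouchEvent, touch_stimuli
from wormstim.mechano import (
    collision_stimulus,
    default_max_range,
    distribute_surface_force,
    force_profile,
    gauss,
    plate_tap_stimuli,
    propagate_to_neurons,
)


def gentle(u, phi, amplitude=10.0, sigma=0.05):
    return TouchEvent(kind="gentle", amplitude=amplitude, onset=0.0,
                      duration=1.0, point=(u, phi), sigma=sigma)


# ---------------------------------------------------------------------------
# temporal profiles
# ---------------------------------------------------------------------------

def test_profile_zero_before_onset():
    ev = TouchEvent(kind="gentle", amplitude=10, onset=2.0, duration=1.0,
                    point=(0.5, 0.0))
    assert force_profile(ev, 1.99) == 0.0
    assert force_profile(ev, -5.0) == 0.0


def test_gentle_amplitude_mid_hold():
    ev = TouchEvent(kind="gentle", amplitude=10.0, onset=1.0, duration=1.0,
                    point=(0.5, 0.0))
    assert force_profile(ev, 1.5) == pytest.approx(10.0)


def test_harsh_has_steeper_ramps_than_gentle():
    g = TouchEvent(kind="gentle", amplitude=10, onset=0, duration=1,
                   point=(0.5, 0.0))
    h = TouchEvent(kind="harsh", amplitude=100, onset=0, duration=1,
                   point=(0.5, 0.0))
    assert g.ramp_times()[0] > h.ramp_times()[0]
    # early into the ramp the harsh profile has already reached full force
    assert force_profile(h, 0.06) == pytest.approx(100.0)
    assert force_profile(g, 0.06) < 10.0


@pytest.mark.parametrize("kind,amplitude,duration", [
    ("gentle", 10.0, 1.0),
    ("harsh", 100.0, 0.4),
    ("gentle", 3.0, 2.5),
])
def test_trapezoid_integral_matches_quadrature(kind, amplitude, duration):
    ev = TouchEvent(kind=kind, amplitude=amplitude, onset=0.5,
                    duration=duration, point=(0.5, 0.0))
    rise, hold, fall = ev.ramp_times()
    expected = amplitude * (hold + (rise + fall) / 2.0)
    breaks = [0.5, 0.5 + rise, 0.5 + rise + hold, 0.5 + duration]
    got, _ = quad(lambda t: float(force_profile(ev, t)), 0.0,
                  1.0 + duration, points=breaks, limit=200)
    assert got == pytest.approx(expected, abs=1e-9)


def test_plate_tap_bell_peaks_at_amplitude():
    ev = TouchEvent(kind="plate_tap", amplitude=50.0, onset=1.0, duration=0.5,
                    point=None)
    t = np.linspace(0.5, 2.0, 2001)
    vals = force_profile(ev, t)
    assert vals.max() == pytest.approx(50.0)
    assert t[vals.argmax()] == pytest.approx(1.25, abs=1e-3)
    assert vals[t < 1.0].max() == 0.0


# ---------------------------------------------------------------------------
# Gaussian spreading over the cuticle
# ---------------------------------------------------------------------------

def test_gaussian_closed_forms(straight_state):
    sigma = 0.05
    # load directly on top of a cuticle node
    node = straight_state.cuticle_world[100]
    fmap = distribute_surface_force(1.0, node, straight_state, sigma=sigma)
    assert fmap[100] == pytest.approx(1.0 / (sigma * math.sqrt(2 * math.pi)))
    # a node at distance d carries Gauss(d)/Gauss(0) of the peak
    d = np.linalg.norm(straight_state.cuticle_world - node, axis=1)
    j = int(np.argmin(np.abs(d - sigma)))
    assert fmap[j] == pytest.approx(
        fmap[100] * math.exp(-0.5 * (d[j] / sigma) ** 2))


def test_spreading_matches_brute_force(straight_state):
    sigma, cutoff = 0.05, 1e-3
    point = straight_state.cuticle_world[42] + np.array([0.01, 0.005, 0.0])
    fmap = distribute_surface_force(7.0, point, straight_state, sigma, cutoff)
    peak = 1.0 / (sigma * math.sqrt(2 * math.pi))
    for i, node in enumerate(straight_state.cuticle_world):
        d = math.dist(point, node)
        w = math.exp(-0.5 * (d / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        expected = 7.0 * w if w / peak >= cutoff else 0.0
        assert fmap[i] == pytest.approx(expected, rel=1e-12, abs=0.0)


def test_far_point_warns_and_returns_empty(straight_state):
    with pytest.warns(UserWarning, match="3 sigma"):
        fmap = distribute_surface_force(
            1.0, np.array([10.0, 10.0, 0.0]), straight_state)
    assert (fmap == 0).all()


# ---------------------------------------------------------------------------
# inverse-distance propagation
# ---------------------------------------------------------------------------

def test_inverse_proportionality_two_neurons(straight_state, registry):
    """A single loaded node stimulates neurons inversely to their distance."""
    fmap = np.zeros(330)
    fmap[150] = 5.0
    node = straight_state.cuticle_world[150]
    out = propagate_to_neurons(fmap, straight_state, registry, max_range=None)
    for name, value in out.items():
        geom = straight_state.neuron_world[name]
        d = np.linalg.norm(geom - node, axis=1).min()
        assert value == pytest.approx(5.0 / max(d, 1e-4), rel=1e-9)


def test_symmetric_dorsal_tail_touch_equal_plm(straight_state, registry):
    ev = gentle(0.9, 0.0)
    out = touch_stimuli(ev, straight_state, registry, np.array([0.5]))
    assert out["PLML"][0] == pytest.approx(out["PLMR"][0], rel=1e-6)
    assert out["PLML"][0] > 0


def test_linearity_and_superposition(straight_state, registry):
    t = np.array([0.5])
    a = touch_stimuli(gentle(0.3, 90.0), straight_state, registry, t)
    a2 = touch_stimuli(gentle(0.3, 90.0, amplitude=20.0), straight_state,
                       registry, t)
    b = touch_stimuli(gentle(0.7, 180.0), straight_state, registry, t)
    for name in a:
        assert a2[name][0] == pytest.approx(2.0 * a[name][0], rel=1e-9)
    # superposition: distributing both forces then propagating equals the sum
    from wormstim.mechano import resolve_application_point
    pa = resolve_application_point(gentle(0.3, 90.0), straight_state)
    pb = resolve_application_point(gentle(0.7, 180.0), straight_state)
    fmap = (distribute_surface_force(10.0, pa, straight_state)
            + distribute_surface_force(10.0, pb, straight_state))
    both = propagate_to_neurons(fmap, straight_state, registry)
    for name in both:
        assert both[name] == pytest.approx(
            a[name][0] + b[name][0], rel=1e-9, abs=1e-12)


def test_pipeline_matches_brute_force_triple_loop(straight_state, registry):
    """Spreading + propagation equals an exhaustive python-loop oracle."""
    sigma, cutoff, eps = 0.05, 1e-3, 1e-4
    rng = np.random.default_rng(7)
    max_range = default_max_range(sigma, cutoff)
    peak = gauss(0.0, sigma)
    for _ in range(5):
        u, phi = rng.uniform(0.1, 0.9), rng.uniform(0, 360)
        ev = gentle(float(u), float(phi))
        got = touch_stimuli(ev, straight_state, registry, np.array([0.5]))
        from wormstim.mechano import resolve_application_point
        p = resolve_application_point(ev, straight_state)
        for name in ["ALML", "PLMR", "AVM", "PVDL", "BDUR"]:
            geom = straight_state.neuron_world[name]
            total = 0.0
            for c in straight_state.cuticle_world:
                w = math.exp(-0.5 * (math.dist(p, c) / sigma) ** 2) \
                    / (sigma * math.sqrt(2 * math.pi))
                if w / peak < cutoff:
                    continue
                dmin = min(math.dist(g, c) for g in geom)
                if dmin > max_range:
                    continue
                total += 10.0 * w / max(dmin, eps)
            assert got[name][0] == pytest.approx(total, rel=1e-9, abs=1e-12)


def test_locality_monotone_single_node(straight_state, registry):
    """Moving a single-node load away from a neuron never raises its input."""
    name = "ALML"
    geom = straight_state.neuron_world[name]
    d = np.linalg.norm(
        straight_state.cuticle_world[:, None, :] - geom[None, :, :],
        axis=2).min(axis=1)
    order = np.argsort(d)
    prev = np.inf
    for idx in order[:50]:
        fmap = np.zeros(330)
        fmap[idx] = 1.0
        val = propagate_to_neurons(fmap, straight_state, registry,
                                   max_range=None)[name]
        assert val <= prev + 1e-12
        prev = val


def test_longitudinal_sweep_orders_touch_receptors(straight_state, registry):
    """Sweeping touch along the body: AVM peaks near the head and vanishes at
    the tail, PLML the reverse, PVM peaks mid-body."""
    us = np.linspace(0.05, 0.95, 19)
    series = {n: [] for n in ("AVM", "PVM", "PLML")}
    for u in us:
        out = touch_stimuli(gentle(float(u), 180.0), straight_state, registry,
                            np.array([0.5]))
        for n in series:
            series[n].append(float(out[n][0]))
    peak_u = {n: us[int(np.argmax(v))] for n, v in series.items()}
    assert peak_u["AVM"] < peak_u["PVM"] < peak_u["PLML"]
    assert series["AVM"][-1] == 0.0  # touch at the tail does not reach AVM
    assert series["PLML"][0] == 0.0  # touch at the nose does not reach PLM


# ---------------------------------------------------------------------------
# plate tap and collisions
# ---------------------------------------------------------------------------

def test_plate_tap_identical_for_all_mechanosensory(registry):
    t = np.linspace(0.0, 1.0, 101)
    out = plate_tap_stimuli(80.0, 0.5, registry, t, onset=0.25)
    names = set(out)
    assert names == set(registry.neurons_with_modality("mechano"))
    ref = out["ALML"]
    assert ref.max() == pytest.approx(80.0)
    for series in out.values():
        assert np.array_equal(series, ref)
    assert "ASEL" not in out  # chemosensory-only neuron receives nothing


def test_collision_equals_touch_pipeline(straight_state, registry):
    point = straight_state.cuticle_world[25]
    col = collision_stimulus(point, 40.0, straight_state, registry)
    fmap = distribute_surface_force(40.0, point, straight_state)
    ref = propagate_to_neurons(fmap, straight_state, registry)
    assert col == ref
    double = collision_stimulus(point, 80.0, straight_state, registry)
    for name in col:
        assert double[name] == pytest.approx(2.0 * col[name], rel=1e-9)


def test_zero_force_collision_is_noop(straight_state, registry):
    assert collision_stimulus(
        straight_state.cuticle_world[0], 0.0, straight_state, registry) == {}
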