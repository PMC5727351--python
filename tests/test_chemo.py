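"""Chemical fields, drop diffusion and sensilla routing."""

import math
import warnings

import numpy as np
import pytest

from wormstim import pose_worm
from wormstim.chemo import (
    DropField,
    PointSourceField,
    QuadrantField,
    RingField,
    chemo_stimuli,
    diffuse,
    drop_concentration,
    eval_static_field,
    init_drop,
    sample_drop,
)
from wormstim.geometry import KinematicState, Undulation


def quadrant_layout():
    """Quadrant assay: biotin quadrant, NaCl barrier, ethanol quadrant."""
    return QuadrantField(
        quadrants=(("butanone", 30.0), ("quinine", 10.0),
                   ("biotin", 44.0), ("ethanol", 60.0)),
        barrier=("NaCl", 20.0),
        barrier_width=2.0,
    )


# ---------------------------------------------------------------------------
# static fields
# ---------------------------------------------------------------------------

def test_quadrant_concentrations_exact():
    spec = quadrant_layout()
    out = eval_static_field(spec, [(-5.0, -5.0)])  # biotin quadrant
    assert out["biotin"][0] == 44.0  # bit-for-bit pass-through
    assert out["NaCl"][0] == 0.0
    assert out["ethanol"][0] == 0.0
    out = eval_static_field(spec, [(5.0, -5.0)])
    assert out["ethanol"][0] == 60.0
    out = eval_static_field(spec, [(0.5, -5.0)])  # inside the barrier strip
    assert out["NaCl"][0] == 20.0
    assert out["biotin"][0] == 0.0


def test_quadrant_boundary_tie_resolves_to_barrier():
    spec = QuadrantField(
        quadrants=(("butanone", 30.0), ("quinine", 10.0),
                   ("biotin", 44.0), ("ethanol", 60.0)),
        barrier=("NaCl", 20.0), barrier_width=0.0)
    out = eval_static_field(spec, [(0.0, 5.0)])
    assert out["NaCl"][0] == 20.0


def test_point_source_closed_forms():
    spec = PointSourceField("NaCl", c0=25.0, lambda_c=3.0, center=(1.0, -2.0))
    assert eval_static_field(spec, [(1.0, -2.0)])["NaCl"][0] == pytest.approx(25.0)
    r = math.sqrt(2.0) * 3.0  # r^2 = 2 lambda^2
    out = eval_static_field(spec, [(1.0 + r, -2.0)])
    assert out["NaCl"][0] == pytest.approx(25.0 / math.e)


def test_point_source_radially_monotone():
    spec = PointSourceField("NaCl", c0=25.0, lambda_c=3.0)
    rs = np.linspace(0, 20, 200)
    vals = eval_static_field(spec, np.stack([rs, np.zeros_like(rs)], 1))["NaCl"]
    assert (np.diff(vals) < 0).all()


def test_ring_annulus_membership():
    spec = RingField("CuSO4", 12.0, r_inner=5.0, r_outer=8.0)
    pts = [(0, 0), (6.5, 0), (0, -7.9), (9, 0)]
    out = eval_static_field(spec, pts)["CuSO4"]
    assert list(out) == [0.0, 12.0, 12.0, 0.0]


def test_point_outside_plate_reads_zero():
    spec = PointSourceField("NaCl", c0=25.0, lambda_c=50.0, plate_diameter=50.0)
    out = eval_static_field(spec, [(40.0, 0.0)])
    assert out["NaCl"][0] == 0.0


# ---------------------------------------------------------------------------
# drop diffusion
# ---------------------------------------------------------------------------

def small_drop():
    return init_drop(center=(0.0, 0.0), c0=50.0, radius=0.25, spacing=0.05,
                     plate_diameter=10.0, D=1e-3)


def test_uniform_field_unchanged_by_diffusion():
    f = DropField("x", np.full((64, 64), 3.0), 0.05, (0.0, 0.0), D=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = diffuse(f, 1.0)
    assert np.array_equal(g.C, f.C)


def test_mass_conserved_over_100_steps():
    f = small_drop()
    m0 = f.total_mass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(100):
            f = diffuse(f, 1.0)
    assert f.total_mass == pytest.approx(m0, rel=1e-6)


def test_grid_matches_heat_kernel_within_2_percent():
    f = small_drop()
    T = 100.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(50):
            f = diffuse(f, T / 50)
    sig = math.sqrt(0.25**2 + 2 * f.D * T)
    rs = np.linspace(0.0, 3 * sig, 30)
    pts = np.stack([rs, np.zeros_like(rs)], 1)
    grid = sample_drop(f, pts)
    exact = drop_concentration((0, 0), 50.0, 0.25, f.D, T, pts)
    assert np.max(np.abs(grid - exact) / exact) < 0.02


def test_variance_grows_by_4_D_dt():
    f = small_drop()
    def variance(fld):
        n = fld.C.shape[0]
        xs = np.arange(n) * fld.spacing
        tot = fld.C.sum()
        mx = (fld.C.sum(0) * xs).sum() / tot
        my = (fld.C.sum(1) * xs).sum() / tot
        return ((fld.C.sum(0) * (xs - mx) ** 2).sum()
                + (fld.C.sum(1) * (xs - my) ** 2).sum()) / tot
    dt = 5.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = diffuse(f, dt)
    assert variance(g) - variance(f) == pytest.approx(4 * f.D * dt, rel=0.01)


def test_undersampled_kernel_warns():
    f = small_drop()
    with pytest.warns(UserWarning, match="undersampled"):
        diffuse(f, 1e-4)


def test_invalid_drop_parameters():
    with pytest.raises(ValueError):
        init_drop((0, 0), c0=1.0, radius=-1.0)
    with pytest.raises(ValueError):
        diffuse(small_drop(), 0.0)


# ---------------------------------------------------------------------------
# sensilla routing
# ---------------------------------------------------------------------------

def test_uniform_plate_all_chemosensory_equal(straight_state, registry):
    def const_field(pts):
        return np.full(len(pts), 17.0)
    const_field.substance = "NaCl"
    out = chemo_stimuli([const_field], straight_state, registry)
    chemo_neurons = {n for n, _ in out}
    assert chemo_neurons == set(registry.neurons_with_modality("chemo"))
    assert all(v == 17.0 for v in out.values())


def test_head_and_tail_read_their_own_regions(mesh, registry):
    """Worm straddling the barrier: amphid (ADFL) in the NaCl strip while the
    phasmid (PHAL) still reads the biotin quadrant."""
    state = pose_worm(mesh, registry, KinematicState(
        t=0.0, head_position=(-0.5, -3.0), heading=0.0,
        undulation=Undulation(amplitude=0.0)))
    out = chemo_stimuli([quadrant_layout()], state, registry)
    assert out[("ADFL", "NaCl")] == 20.0
    assert out[("ADFL", "biotin")] == 0.0
    assert out[("PHAL", "biotin")] == 44.0
    assert out[("PHAL", "NaCl")] == 0.0


def test_multi_sensilla_neuron_takes_maximum(straight_state, registry):
    """Field values are routed per sensillum; a neuron in several sensilla
    keeps the largest sample."""
    spec = PointSourceField("NaCl", c0=10.0, lambda_c=0.3, center=(0.0, 0.0))
    out = chemo_stimuli([spec], straight_state, registry)
    for (neuron, sub), val in out.items():
        expected = max(
            eval_static_field(
                spec, registry_sensillum_points(straight_state, registry,
                                                neuron))["NaCl"].max()
            for _ in [0])
        assert val == pytest.approx(expected, rel=1e-12)


def registry_sensillum_points(state, registry, neuron):
    names = [s for s, rec in registry.sensilla.items()
             if neuron in rec.members]
    return np.vstack([state.sensilla_world[s][:2] for s in names])
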