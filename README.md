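# wormstim

Per-neuron sensory stimulus generation for virtual *C. elegans* behavioral
assays.

Neural simulations of *C. elegans* need realistic sensory input: when a
virtual worm is touched, crosses a chemical quadrant plate, feels a thermal
gradient, is shocked, illuminated, or simply bends while crawling, each of
its 302 neurons should receive a stimulus value that depends on what the
assay does, where the worm is, and how its sensory apparatus is wired.
`wormstim` turns a behavioral-experiment description (an XML timeline of
events) plus an open-loop kinematic worm body into exactly that: a table of
per-timestep, per-neuron, per-modality (and per-substance) stimulus values,
covering six stimulus families — mechano-, chemo-, thermo-, galvano- and
photosensation, and proprioception. It is aimed at people building neural
network or neuron-model simulations of the worm who want assay-driven input
time series without running a soft-body physics engine.

## Models

**Body and routing.** The worm is a parametric tube (length 1 mm, maximum
radius 0.04 mm) whose cuticle carries 330 mesh nodes in 33 axial slices.
The default registry instantiates the 302 hermaphrodite neurons with
body-relative soma positions, the six touch receptor neurons (ALML/R, AVM,
PLML/R, PVM) with long mechanosensory processes, 26 sensilla (20 in the
head) hardwired to their member neurons, and 95 body-wall muscles in 8
longitudinal bundles with a synthetic neuromuscular table in which 75
ventral-cord motor neurons innervate the 79 muscles posterior to the head.
Everything is overridable from CSV tables.

**Mechanosensation.** A surface force F_p at point p is spread over the
cuticle nodes with a Gaussian weight, F_c = Σ_p F_p · Gauss(d(p, c)), and
each loaded node stimulates a neuron through the inverse distance to the
nearest point n of the neuron's discretized geometry:

    Stimuli_N = Σ_{c ∈ C3D}  F_c / d(n, c),   n = argmin_{i ∈ N3D} d(i, c).

Gentle touches use soft trapezoid ramps peaking near 10 μN, harsh touches
steep ramps near 100 μN, plate taps deliver one bell-shaped profile to every
mechanosensory neuron, and obstacle collisions feed the same spatial
pipeline with a penetration-depth contact force.

**Chemosensation.** Quadrant plates with barrier strips, osmotic rings and
steady point sources c = c0·exp(−r²/2λ²) are static; a chemical drop
diffuses by ∂C/∂t = D∇²C, solved by Gaussian blurring. Sensilla sample the
field at their posed positions and forward concentrations to their member
neurons.

**Thermosensation.** Global ramps (held after the event), linear plate
gradients and Gaussian heat points; the branched PVD/FLP neurons report the
minimum/maximum temperature over their dendritic arbor.

**Galvano/photosensation.** Box-function electric pulse trains to all 302
neurons; circular constant-intensity light beams to the neurons whose soma
lies inside the beam.

**Proprioception.** Signed 3-point circumcircle curvature at the 33
centerline points, routed to curvature-sensing neurons (averaged over a
neuron's sensing segments), and connection-weighted mean muscle strain
routed to motor neurons.

## Worked example

```bash
$ wormstim make-fixtures assays
$ wormstim validate assays/quadrants.xml
OK: 1 events (0 predefined, 1 runtime), 0 obstacles, dt=0.02s, t_end=16.0s
$ wormstim run assays/quadrants.xml --out stimuli.csv
wrote 224280 rows to stimuli.csv (chemo=224280)
$ head -3 stimuli.csv
t,neuron,modality,channel,value
0.0,ADEL,chemo,NaCl,0.0
0.0,ADEL,chemo,biotin,44.0
```

The worm starts in a biotin quadrant (44 mM) and crawls across a 20 mM NaCl
barrier into a 60 mM ethanol quadrant: at t = 0 the anterior deirid neuron
ADEL reads the biotin concentration of its quadrant and zero for every other
substance. Over the run, head neurons (e.g. ADFL) see the sequence
biotin → NaCl → ethanol before tail neurons (e.g. PHAL) do, because the
amphids cross each boundary first.

The same pipelines are available as a library:

```python
import numpy as np, wormstim as ws

mesh = ws.build_body_mesh()
registry = ws.build_default_registry(mesh=mesh)
state = ws.pose_worm(mesh, registry, ws.reference_state())

event = ws.TouchEvent(kind="gentle", amplitude=10.0, onset=0.0,
                      duration=1.0, point=(0.9, 0.0))  # dorsal tail touch
out = ws.touch_stimuli(event, state, registry, np.array([0.5]))
for n in ("PLML", "PLMR", "PVM", "AVM"):
    print(f"{n}: {out[n][0]:.1f}")
```

```
PLML: 122897.9
PLMR: 122897.9
PVM: 1101.3
AVM: 0.0
```

A symmetric dorsal touch at the tail stimulates the two posterior touch
receptors identically (their processes run under the touch point on either
side), reaches the mid-body receptor PVM only weakly, and does not reach the
anterior receptor AVM at all. Stimulus units are μN·mm⁻¹ (force × inverse
distance), deliberately not renormalized — scaling is left to downstream
neuron models.

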