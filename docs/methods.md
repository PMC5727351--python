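# Methods

This note documents the models implemented in `wormstim`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.

## Body model and kinematics

The worm body is a parametric tube: axial coordinate `u ∈ [0, 1]` (0 = nose,
1 = tail), angular coordinate `phi` in degrees on the transversal plane
(0 = dorsal midline, 90 = left, 180 = ventral, 270 = right), and a radial
coordinate expressed as a fraction of the local radius. The radius profile
is elliptic, `r(u) = r_max·sqrt(4u(1−u))`, zero at both tips, with
`r_max = 0.04 mm` and body length 1 mm by default. The cuticle carries 330
surface nodes grouped ring-per-slice into 33 axial slices (10 nodes per ring
at the defaults; for node counts not divisible by the slice count the
remainder is spread one node per ring from the nose backwards). The slice
centroids are the 33 centerline points used for curvature.

Locomotion is an open-loop planar undulation: the centerline is a travelling
sinusoid of amplitude `A` (default 0.1 mm), wavelength `λ` (0.65 mm),
frequency `f` (0.3 Hz) and forward speed (0.15 mm/s) around the heading
axis, and all body-relative points are swept around it using the local
tangent frame (the plate normal spans `phi = 0`, the in-plane left-of-heading
direction `phi = 90`). This stands in for a soft-body physics simulation;
it supplies every quantity the stimulus models consume (world positions,
distances, slice membership, muscle lengths) but conserves neither arc
length under bending nor contact mechanics — a worm pressed against an
obstacle keeps its prescribed trajectory. Consequently the packaged
collision scenario is read as "force the obstacle exerts at the prescribed
pose", not as a trajectory prediction.

The default gait parameters are in the range reported for crawling worms
(undulation wavelength somewhat below one body length, fractions of a hertz,
speeds of 0.1–0.4 mm/s); scenario files override speed and frequency per
assay.

## Anatomical registry

The 302 hermaphrodite neurons are generated from the standard class
decomposition (99 left/right pairs including CAN, 29 unpaired neurons
including the 20 pharyngeal ones, and 75 ventral-cord motor neurons
AS1–11, DA1–9, DB1–7, DD1–6, VA1–12, VB1–11, VC1–6, VD1–13). Soma
placements are coarse and literature-informed — head-ganglion classes spread
over `u ∈ [0.06, 0.16]`, tail ganglia above 0.85, ventral-cord motor
neurons spread over `u ∈ [0.25, 0.9]` by class index — and are explicitly
configuration, not ground truth; a CSV override table replaces any record.

Only the six touch receptor neurons carry long mechanosensory process
polylines (ALM/AVM anterior half, PVM mid-body, PLM posterior part),
discretized at 20 points each. The branched PVD/FLP dendritic arbors used by
the thermal min/max rule are kept in a separate field (40 points spanning
the body and always including the soma), as are the elongated axon spans of
the A/B-type motor neurons used for curvature averaging (±0.06 body lengths
around the soma, 7 points) — this keeps "neurons with processes" a
well-defined six-element set while still giving extended geometry to the
neurons that need it.

Sensilla follow standard WormAtlas-style assignments: per side one amphid
(housing ADF, ADL, AFD, ASE, ASG, ASH, ASI, ASJ, ASK, AWA, AWB, AWC), three
inner-labial and three outer-labial sensilla, two cephalic sensilla, and an
anterior deirid in the head; a phasmid (PHA, PHB), a postdeirid (PDE) and a
"caudal" sensillum housing PHC posteriorly. The caudal pair completes the
three posterior pairs and is a declared approximation.

The neuromuscular table is synthetic: 95 muscles in 8 bundles (left/right ×
dorsal/ventral × medial/lateral; 12 per bundle except 11 in the
ventral-left-lateral one), the first two muscles of each bundle counted as
head muscles, and each of the 75 motor neurons wired to the posterior
muscles of its dorsal or ventral bundles whose span overlaps its axial
neighborhood (weight 2 for the nearest muscle, 1 otherwise, plus a coverage
pass so every posterior muscle is innervated). This reproduces the 75-neuron
/ 79-muscle structure without shipping a connectome table; real innervation
weights can be loaded from CSV.

## Mechanosensation

A touch applies a force profile `F_p(t)` at a body point. Profiles are
trapezoids — rise and fall each a quarter of the event duration for gentle
touch (default amplitude 10 μN), a twentieth for harsh touch (100 μN) — and
a Gaussian bell for plate taps (peak at the configured amplitude, width 1/6
of the event so ±3 widths fill the window). The exact ramp shapes are a
design choice; only "soft" versus "steep" is constrained.

Spatially, the force is spread over the cuticle nodes with a normalized
Gaussian of the 3-D distance, `σ = 0.05 mm` by default (comparable to the
body radius), and weights below `cutoff = 10⁻³` of the peak are zeroed.
Each loaded node then contributes `F_c / max(d, ε)` to every mechanosensory
neuron, where `d` is the distance from the node to the nearest point of the
neuron's soma-plus-process geometry and `ε = 10⁻⁴ mm` caps the singularity
when a node coincides with neuron geometry. Node-to-neuron weights are
zeroed beyond `R = σ·sqrt(2·ln(1/cutoff))` (≈ 0.19 mm at the defaults) — the
radius at which the spreading Gaussian itself falls below the cutoff. This
locality cutoff is the package's choice: pure inverse distance decays so
slowly that a head collision would register at tail neurons at ~15 % of the
head response, whereas the observed behavior is that distant neurons stay
silent and a touch receptor's response vanishes outside its process span.
Passing `max_range=None` restores pure 1/d propagation. Stimulus units are
μN·mm⁻¹ and are deliberately not renormalized.

Body-frame touch events are evaluated on the straight reference pose (the
weights depend only on body-intrinsic distances, so they are precomputed
before the run); collisions are evaluated on the posed worm each step, with
contact modeled as the deepest cuticle node inside a disc obstacle and a
force of stiffness (default 1 μN per μm) times penetration depth.

## Chemosensation

Quadrant plates carry one substance per quadrant plus a cross-shaped barrier
strip on the dividing axes (default width 2 mm) with its own substance;
points exactly on a boundary resolve to the barrier, since the barrier
physically overlays it. Osmotic rings are annuli at fixed concentration.
Static point sources follow the steady Gaussian gradient
`c = c0·exp(−r²/2λ²)`. None of these diffuse during an assay.

The drop test solves the 2-D diffusion equation by Gaussian blurring:
one step of length `dt` convolves the grid with an isotropic Gaussian kernel
of variance `2·D·dt`, with a reflective plate boundary so total mass is
conserved (verified to 10⁻¹⁴ relative over 100 steps). The drop is
initialized as a Gaussian blob (peak concentration and width configurable;
default 0.25 mm width, `D = 10⁻⁴ mm²/s`, 0.05 mm grid spacing). Because
blurs compose, the blob admits a closed form with variance `σ0² + 2Dt`; the
experiment engine samples this closed form each timestep instead of stepping
the grid, which is exactly equivalent away from the plate boundary (drops
are delivered near the worm, tens of millimetres from the edge) and avoids
per-timestep blurs whose kernel would be far narrower than the grid spacing.
The grid implementation is retained as API and is cross-checked against the
closed form and the 2-D heat kernel in the tests (agreement within 2 %
inside three standard deviations).

Delivery ignores sensing height: fields are two-dimensional and each
sensillum samples at its plate-plane projection. Every member neuron of a
sensillum receives the sampled value; a neuron belonging to several sensilla
receives the maximum. All sensilla classes participate, not only the
canonically chemosensory ones.

## Thermosensation

Global temperature changes ramp linearly from a start to an end value over
the event window, hold the end value afterwards, and reach every
thermosensory neuron identically regardless of position. Linear gradients
interpolate affinely across the plate; local heating is a steady circular
Gaussian gradient (the functional form is a choice — only "circular
gradient" is constrained — and mirrors the chemical point source). Spatial
fields are steady-state and not updated in time, and the worm's body does
not insulate or transport heat.

Point-rule neurons sample at their sensillum position when they belong to
one (alphabetically first sensillum as the deterministic tie-break), else at
the soma. PVD reports the minimum and FLP the maximum over their discretized
arbor, reflecting their cold-shock and noxious-heat roles.

## Galvano- and photosensation

Electric shocks are box-function pulse trains (amplitude in nA, pulse
repetition frequency, pulse width ≤ one period) delivered identically to all
302 neurons — targeted charge delivery is not achievable in a plate assay.
Light pulses are a single temporal box (not a train) of constant intensity
inside a circular beam (default radius 0.2 mm, duration 190 ms); a neuron is
illuminated when its soma lies within the beam radius on the plate plane,
boundary inclusive. Beam membership uses somata only (processes are
ignored), the body does not attenuate the beam, and wavelength is carried as
metadata for downstream neuron models. Because the kinematics are open-loop,
beam membership for body-relative beams is frozen at the pose of the event
onset and the series is precomputed.

## Proprioception

Curvature is the signed circumcircle (Menger) curvature of each interior
centerline point and its two neighbors, restricted to the plate plane;
endpoints copy their interior neighbor, and degenerate neighborhoods
(duplicate consecutive points) yield zero with a warning. The sign is
positive for bending toward the right of the direction of travel, which this
package labels the ventral side; both the sign convention and the endpoint
replication are choices. Point neurons read the sample nearest their soma;
neurons with extended geometry average the samples nearest each geometry
point, i.e. the summed response is normalized by the number of sensing
segments. By default the touch receptors and the A/B-type motor neuron
classes (AS, DA, DB, VA, VB) sense curvature; the set is overridable through
registry modality flags.

Muscle stretch is the dimensionless strain `(length − rest)/rest` of each
muscle's posed polyline, routed to motor neurons as the connection-weighted
mean over their innervated muscles. Strain keeps the rest configuration at
exactly zero and the stimulus bounded by the extreme strains. No
head-to-tail efficacy gradient is applied; such compensation is treated as a
property of downstream neuron sensitivity.

## Experiment engine

Events divide into predefined stimuli (gentle/harsh touch, plate tap, global
temperature change, electric shock, light pulse), computed before the loop,
and runtime stimuli (collisions, curvature and stretch sensing, all chemical
layouts and drops, thermal gradients and heat points), computed against the
posed worm each timestep. Default timestep 5 ms and duration 60 s; the
packaged scenario files use 10–20 ms steps over 4–16 s runs (a few hundred
to a thousand steps each), which resolves every profile they contain while
keeping the full scenario suite to seconds of compute. Rows are emitted for
the timesteps inside each event's active window and the neurons of the
event's modality; the table is sorted by `(t, neuron, modality, channel)`
and the whole pipeline is deterministic — identical spec and seed give
byte-identical CSVs (the engine itself draws no random numbers; the seed is
plumbed for forward compatibility and for tools built on top).

## Known limitations

- Open-loop kinematics: no feedback from stimuli to motion, no contact
  response, no arc-length preservation under bending.
- Soma placements, process spans and the neuromuscular table are synthetic
  defaults built to the documented structural counts, not measured anatomy;
  conclusions about individual neuron magnitudes should not be read off the
  defaults.
- The drop's closed-form evaluation ignores the reflective plate boundary;
  for drops within a few diffusion lengths of the plate edge, step the grid
  instead.
- Substance pharmacology is out of scope: an immobilizing substance does not
  alter the kinematics, and the worm does not perturb the fields it crawls
  through.
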