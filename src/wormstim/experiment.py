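"""Behavioral-experiment engine: XML parsing, scheduling and the run loop.

An experiment file describes the assay plate, the worm's initial pose and
gait, the scheduled stimulus events and any obstacles.  Events fall into two
groups.  *Predefined* stimuli (gentle/harsh touch, plate-tap, global
temperature change, electric shock, light pulse) do not depend on the worm's
trajectory and are computed before the simulation loop; body-frame touch
weights are evaluated once on the straight reference pose and scaled by the
temporal force profile.  *Runtime* stimuli (collisions, curvature and
muscle-stretch proprioception, chemical layouts and drops, thermal
gradients) need the posed worm and are evaluated every timestep.

The engine's sole output is the stimulus table: one row per
``(t, neuron, modality, channel)`` with the scalar stimulus value, written
as long-form CSV (or a wide per-neuron matrix).  Runs are deterministic:
identical spec and seed give byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

from . import chemo, electro_photo, mechano, proprio, thermo
from .geometry import (
    BodyMesh,
    KinematicState,
    Undulation,
    build_body_mesh,
    pose_worm,
    reference_state,
)
from .registry import Registry, build_default_registry

__all__ = [
    "ExperimentError",
    "WormConfig",
    "Obstacle",
    "EventSpec",
    "ExperimentSpec",
    "parse_experiment",
    "write_experiment",
    "classify_events",
    "run",
    "write_table",
    "read_table",
    "PREDEFINED_KINDS",
    "RUNTIME_KINDS",
]

DEFAULT_DT = 0.005  # s
DEFAULT_T_END = 60.0  # s
DEFAULT_STIFFNESS = 1000.0  # uN/mm (1 uN per um of disc penetration)


class ExperimentError(ValueError):
    """Raised for malformed or invalid experiment descriptions."""


@dataclass(frozen=True)
class WormConfig:
    """Initial pose and open-loop gait of the worm."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0  # radians
    length: float = 1.0  # mm
    amplitude: float = 0.1  # mm
    wavelength: float = 0.65  # mm
    frequency: float = 0.3  # Hz
    speed: float = 0.15  # mm/s

    def undulation(self) -> Undulation:
        return Undulation(self.amplitude, self.wavelength,
                          self.frequency, self.speed)

    def state_at(self, t: float) -> KinematicState:
        head = (
            self.x + self.speed * t * math.cos(self.heading),
            self.y + self.speed * t * math.sin(self.heading),
        )
        return KinematicState(t=t, head_position=head, heading=self.heading,
                              undulation=self.undulation())


@dataclass(frozen=True)
class Obstacle:
    """Rigid disc on the plate; contact force = stiffness x penetration."""

    x: float
    y: float
    radius: float
    stiffness: float = DEFAULT_STIFFNESS


@dataclass(frozen=True)
class EventSpec:
    """One scheduled stimulus event."""

    kind: str
    onset: float = 0.0
    duration: float | None = None  # None = active until t_end
    params: tuple[tuple[str, float | str], ...] = ()

    def get(self, key, default=None):
        return dict(self.params).get(key, default)


@dataclass(frozen=True)
class ExperimentSpec:
    plate_diameter: float = 50.0
    worm: WormConfig = field(default_factory=WormConfig)
    events: tuple[EventSpec, ...] = ()
    obstacles: tuple[Obstacle, ...] = ()
    dt: float = DEFAULT_DT
    t_end: float = DEFAULT_T_END
    seed: int = 0


PREDEFINED_KINDS = frozenset({
    "touch", "plate_tap", "global_temp", "electric_shock", "light_pulse",
})
RUNTIME_KINDS = frozenset({
    "collision", "proprioception", "osmotic_ring", "quadrants",
    "chem_point_source", "chem_drop", "thermal_gradient", "heat_point",
})


def classify_events(spec: ExperimentSpec) -> tuple[list[EventSpec], list[EventSpec]]:
    """Partition scheduled events into (predefined, runtime) groups."""
    predefined = [e for e in spec.events if e.kind in PREDEFINED_KINDS]
    runtime = [e for e in spec.events if e.kind in RUNTIME_KINDS]
    return predefined, runtime


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

# element -> (event kind, required attrs, optional attrs with defaults)
_EVENT_SCHEMA: dict[str, tuple[str, tuple[str, ...], dict[str, float | str]]] = {
    "touch": ("touch", ("kind", "u", "phi", "amplitude", "onset", "duration"),
              {"sigma": mechano.DEFAULT_SIGMA, "cutoff": mechano.DEFAULT_CUTOFF}),
    "plateTap": ("plate_tap", ("amplitude", "onset", "duration"), {}),
    "quadrants": ("quadrants", ("q1", "q2", "q3", "q4", "barrier"),
                  {"barrierWidth": 2.0}),
    "osmoticRing": ("osmotic_ring", ("substance", "concentration",
                                     "inner", "outer"),
                    {"x": 0.0, "y": 0.0}),
    "chemPointSource": ("chem_point_source",
                        ("substance", "c0", "lambda", "x", "y"), {}),
    "chemDrop": ("chem_drop", ("substance", "amount", "x", "y", "onset"),
                 {"D": 1e-4, "radius": 0.25}),
    "globalTemp": ("global_temp", ("start", "end", "onset", "duration"),
                   {"base": thermo.DEFAULT_BASE_C}),
    "thermalGradient": ("thermal_gradient", ("left", "right"), {}),
    "heatPoint": ("heat_point", ("peak", "x", "y", "decay"),
                  {"base": thermo.DEFAULT_BASE_C}),
    "electricShock": ("electric_shock",
                      ("amplitude", "frequency", "pulseDuration", "onset",
                       "trainDuration"), {}),
    "lightPulse": ("light_pulse", ("intensity", "onset", "duration"),
                   {"radius": 0.2, "wavelength": "", "x": "", "y": "", "u": ""}),
    "proprioception": ("proprioception", (), {"curvature": "on", "stretch": "on"}),
}

_STRING_ATTRS = {"kind", "substance", "q1", "q2", "q3", "q4", "barrier",
                 "curvature", "stretch"}

_KIND_TO_ELEMENT = {v[0]: k for k, v in _EVENT_SCHEMA.items()}

_WORM_ATTRS = {f.name for f in WormConfig.__dataclass_fields__.values()}


def _err(elem, message: str) -> ExperimentError:
    line = getattr(elem, "sourceline", None)
    where = f" (line {line})" if line else ""
    return ExperimentError(f"<{elem.tag}>{where}: {message}")


def _parse_value(name: str, raw: str) -> float | str:
    if name in _STRING_ATTRS:
        return raw
    try:
        return float(raw)
    except ValueError as exc:
        raise ExperimentError(
            f"attribute {name!r}: {raw!r} is not a number") from exc


def _parse_event(elem) -> EventSpec:
    if elem.tag not in _EVENT_SCHEMA:
        raise _err(elem, "unknown event element")
    kind, required, optional = _EVENT_SCHEMA[elem.tag]
    allowed = set(required) | set(optional)
    for attr in elem.attrib:
        if attr not in allowed:
            raise _err(elem, f"unknown attribute {attr!r}")
    params: dict[str, float | str] = {}
    for attr in required:
        if attr not in elem.attrib:
            raise _err(elem, f"missing required attribute {attr!r}")
        params[attr] = _parse_value(attr, elem.attrib[attr])
    for attr, default in optional.items():
        if attr in elem.attrib:
            params[attr] = _parse_value(attr, elem.attrib[attr])
        elif default != "":
            params[attr] = default
    if kind == "light_pulse" and ("u" in params) == ("x" in params):
        raise _err(elem, "specify exactly one of u= or x=/y=")
    onset = float(params.pop("onset", 0.0))
    duration = params.pop("duration", None)
    if kind in {"global_temp"}:  # ramp duration is a parameter, not a window
        params["duration"] = duration
        duration = None
    if kind == "electric_shock":
        duration = params.get("trainDuration")
    return EventSpec(
        kind=kind,
        onset=onset,
        duration=None if duration is None else float(duration),
        params=tuple(sorted(params.items())),
    )


def parse_experiment(path: str) -> ExperimentSpec:
    """Parse and validate a behavioral-experiment XML file."""
    tree = etree.parse(path)
    root = tree.getroot()
    if root.tag != "experiment":
        raise _err(root, "root element must be <experiment>")
    for attr in root.attrib:
        if attr not in {"dt", "tEnd", "seed"}:
            raise _err(root, f"unknown attribute {attr!r}")
    dt = float(root.get("dt", DEFAULT_DT))
    t_end = float(root.get("tEnd", DEFAULT_T_END))
    seed = int(root.get("seed", 0))
    if dt <= 0:
        raise ExperimentError("dt must be > 0")
    if t_end <= 0:
        raise ExperimentError("tEnd must be > 0")

    plate_diameter = 50.0
    worm = WormConfig()
    events: list[EventSpec] = []
    obstacles: list[Obstacle] = []

    for child in root:
        if child.tag is etree.Comment:
            continue
        if child.tag == "plate":
            plate_diameter = float(child.get("diameter", 50.0))
        elif child.tag == "worm":
            for attr in child.attrib:
                if attr not in _WORM_ATTRS:
                    raise _err(child, f"unknown attribute {attr!r}")
            worm = WormConfig(**{k: float(v) for k, v in child.attrib.items()})
        elif child.tag == "events":
            for ev in child:
                if ev.tag is etree.Comment:
                    continue
                events.append(_parse_event(ev))
        elif child.tag == "obstacles":
            for ob in child:
                if ob.tag != "disc":
                    raise _err(ob, "obstacles may only contain <disc>")
                for attr in ob.attrib:
                    if attr not in {"x", "y", "radius", "stiffness"}:
                        raise _err(ob, f"unknown attribute {attr!r}")
                obstacles.append(Obstacle(
                    x=float(ob.attrib["x"]), y=float(ob.attrib["y"]),
                    radius=float(ob.attrib["radius"]),
                    stiffness=float(ob.get("stiffness", DEFAULT_STIFFNESS)),
                ))
        else:
            raise _err(child, "unknown element")

    spec = ExperimentSpec(
        plate_diameter=plate_diameter, worm=worm, events=tuple(events),
        obstacles=tuple(obstacles), dt=dt, t_end=t_end, seed=seed,
    )
    _validate_spec(spec)
    return spec


def _validate_spec(spec: ExperimentSpec) -> None:
    for ev in spec.events:
        if not (0.0 <= ev.onset <= spec.t_end):
            raise ExperimentError(
                f"event {ev.kind!r}: onset {ev.onset} outside [0, {spec.t_end}]")


def write_experiment(spec: ExperimentSpec, path: str) -> None:
    """Serialize a spec back to the XML dialect (round-trips with parse)."""
    root = etree.Element("experiment", dt=repr(spec.dt), tEnd=repr(spec.t_end),
                         seed=str(spec.seed))
    etree.SubElement(root, "plate", diameter=repr(spec.plate_diameter))
    etree.SubElement(root, "worm", **{
        k: repr(getattr(spec.worm, k)) for k in sorted(_WORM_ATTRS)})
    events = etree.SubElement(root, "events")
    for ev in spec.events:
        attrs = {}
        for k, v in ev.params:
            if v is None:
                continue
            attrs[k] = v if isinstance(v, str) else repr(v)
        element = _KIND_TO_ELEMENT[ev.kind]
        _, required, optional = _EVENT_SCHEMA[element]
        if "onset" in required or "onset" in optional:
            attrs["onset"] = repr(ev.onset)
        if ev.kind == "electric_shock":
            attrs.pop("trainDuration", None)
            attrs["trainDuration"] = repr(ev.duration)
        elif ev.duration is not None:
            attrs["duration"] = repr(ev.duration)
        etree.SubElement(events, _KIND_TO_ELEMENT[ev.kind], **attrs)
    if spec.obstacles:
        obstacles = etree.SubElement(root, "obstacles")
        for ob in spec.obstacles:
            etree.SubElement(obstacles, "disc", x=repr(ob.x), y=repr(ob.y),
                             radius=repr(ob.radius),
                             stiffness=repr(ob.stiffness))
    etree.ElementTree(root).write(path, pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# simulation loop
# ---------------------------------------------------------------------------

def _window_steps(times: np.ndarray, onset: float, end: float) -> np.ndarray:
    return np.nonzero((times >= onset - 1e-12) & (times <= end + 1e-12))[0]


class _Rows:
    """Column-wise accumulator for stimulus-table rows."""

    def __init__(self) -> None:
        self.t: list[np.ndarray] = []
        self.neuron: list[np.ndarray] = []
        self.modality: list[np.ndarray] = []
        self.channel: list[np.ndarray] = []
        self.value: list[np.ndarray] = []

    def add_series(self, times: np.ndarray, neuron: str, modality: str,
                   channel: str, values: np.ndarray) -> None:
        n = len(times)
        self.t.append(times)
        self.neuron.append(np.full(n, neuron, dtype=object))
        self.modality.append(np.full(n, modality, dtype=object))
        self.channel.append(np.full(n, channel, dtype=object))
        self.value.append(np.asarray(values, dtype=float))

    def add_step(self, t: float, entries: list[tuple[str, str, str, float]]) -> None:
        if not entries:
            return
        n = len(entries)
        self.t.append(np.full(n, t))
        self.neuron.append(np.array([e[0] for e in entries], dtype=object))
        self.modality.append(np.array([e[1] for e in entries], dtype=object))
        self.channel.append(np.array([e[2] for e in entries], dtype=object))
        self.value.append(np.array([e[3] for e in entries], dtype=float))

    def frame(self) -> pd.DataFrame:
        if not self.t:
            return pd.DataFrame(
                columns=["t", "neuron", "modality", "channel", "value"])
        df = pd.DataFrame({
            "t": np.concatenate(self.t),
            "neuron": np.concatenate(self.neuron),
            "modality": np.concatenate(self.modality),
            "channel": np.concatenate(self.channel),
            "value": np.concatenate(self.value),
        })
        return df.sort_values(
            ["t", "neuron", "modality", "channel"], ignore_index=True)


def _touch_event_from_spec(ev: EventSpec) -> mechano.TouchEvent:
    return mechano.TouchEvent(
        kind=str(ev.get("kind")),
        amplitude=float(ev.get("amplitude")),
        onset=ev.onset,
        duration=float(ev.duration),
        point=(float(ev.get("u")), float(ev.get("phi"))),
        body_relative=True,
        sigma=float(ev.get("sigma", mechano.DEFAULT_SIGMA)),
        cutoff=float(ev.get("cutoff", mechano.DEFAULT_CUTOFF)),
    )


def _static_chem_field(ev: EventSpec, plate_diameter: float):
    if ev.kind == "quadrants":
        def pair(token: str) -> tuple[str, float]:
            sub, conc = str(token).split(":")
            return sub.strip(), float(conc)

        return chemo.QuadrantField(
            quadrants=tuple(pair(ev.get(q)) for q in ("q1", "q2", "q3", "q4")),
            barrier=pair(ev.get("barrier")),
            barrier_width=float(ev.get("barrierWidth", 2.0)),
            plate_diameter=plate_diameter,
        )
    if ev.kind == "osmotic_ring":
        return chemo.RingField(
            substance=str(ev.get("substance")),
            concentration=float(ev.get("concentration")),
            r_inner=float(ev.get("inner")), r_outer=float(ev.get("outer")),
            center=(float(ev.get("x", 0.0)), float(ev.get("y", 0.0))),
            plate_diameter=plate_diameter,
        )
    if ev.kind == "chem_point_source":
        return chemo.PointSourceField(
            substance=str(ev.get("substance")),
            c0=float(ev.get("c0")), lambda_c=float(ev.get("lambda")),
            center=(float(ev.get("x")), float(ev.get("y"))),
            plate_diameter=plate_diameter,
        )
    raise ValueError(ev.kind)


def _thermal_field(ev: EventSpec, plate_diameter: float):
    if ev.kind == "thermal_gradient":
        return thermo.LinearGradient(
            t_left=float(ev.get("left")), t_right=float(ev.get("right")),
            plate_diameter=plate_diameter)
    return thermo.HeatPoint(
        peak=float(ev.get("peak")),
        center=(float(ev.get("x")), float(ev.get("y"))),
        decay=float(ev.get("decay")), base=float(ev.get("base", 20.0)))


def _obstacle_contact(obstacle: Obstacle, cuticle: np.ndarray):
    """Deepest-node disc contact: (point, force uN) or None."""
    d = np.hypot(cuticle[:, 0] - obstacle.x, cuticle[:, 1] - obstacle.y)
    i = int(np.argmin(d))
    penetration = obstacle.radius - d[i]
    if penetration <= 0:
        return None
    return cuticle[i], obstacle.stiffness * penetration


def run(
    spec: ExperimentSpec,
    registry: Registry | None = None,
    mesh: BodyMesh | None = None,
) -> pd.DataFrame:
    """Execute the experiment and assemble the stimulus table.

    Phase 1 precomputes every predefined stimulus series (touch spreading and
    propagation weights on the straight reference pose).  Phase 2 steps the
    open-loop kinematics from 0 to ``t_end`` and evaluates runtime stimuli
    against the posed worm.
    """
    mesh = mesh or build_body_mesh(length_mm=spec.worm.length)
    registry = registry or build_default_registry(mesh=mesh)

    n_steps = int(round(spec.t_end / spec.dt)) + 1
    times = np.round(np.arange(n_steps) * spec.dt, 9)
    rows = _Rows()

    predefined, runtime = classify_events(spec)

    # --- phase 1: predefined stimuli -------------------------------------
    ref_pose = None
    for ev in predefined:
        if ev.kind == "touch":
            if ref_pose is None:
                ref_pose = pose_worm(mesh, registry, reference_state())
            event = _touch_event_from_spec(ev)
            idx = _window_steps(times, ev.onset, ev.onset + float(ev.duration))
            series = mechano.touch_stimuli(event, ref_pose, registry, times[idx])
            for neuron, values in series.items():
                rows.add_series(times[idx], neuron, "mechano", "", values)
        elif ev.kind == "plate_tap":
            idx = _window_steps(times, ev.onset, ev.onset + float(ev.duration))
            series = mechano.plate_tap_stimuli(
                float(ev.get("amplitude")), float(ev.duration), registry,
                times[idx], onset=ev.onset)
            for neuron, values in series.items():
                rows.add_series(times[idx], neuron, "mechano", "", values)
        elif ev.kind == "global_temp":
            gspec = thermo.GlobalTemperature(
                base=float(ev.get("base", 20.0)), start=float(ev.get("start")),
                end=float(ev.get("end")), onset=ev.onset,
                duration=float(ev.get("duration")))
            values = thermo.global_temperature(gspec, times)
            for neuron in registry.neurons_with_modality("thermo"):
                rows.add_series(times, neuron, "thermo", "", values)
        elif ev.kind == "electric_shock":
            espec = electro_photo.ElectricShockSpec(
                amplitude=float(ev.get("amplitude")),
                frequency=float(ev.get("frequency")),
                pulse_duration=float(ev.get("pulseDuration")),
                onset=ev.onset, train_duration=float(ev.duration))
            idx = _window_steps(times, ev.onset, ev.onset + float(ev.duration))
            values = electro_photo.electric_pulse_train(espec, times[idx])
            for neuron in registry.neurons_with_modality("galvano"):
                rows.add_series(times[idx], neuron, "galvano", "", values)
        elif ev.kind == "light_pulse":
            center_u = ev.get("u")
            lspec = electro_photo.LightPulseSpec(
                intensity=float(ev.get("intensity")),
                radius=float(ev.get("radius", 0.2)),
                onset=ev.onset, duration=float(ev.duration),
                center=None if center_u is not None
                else (float(ev.get("x")), float(ev.get("y"))),
                center_u=None if center_u is None else float(center_u),
            )
            # beam membership frozen at the pose of the event onset; under
            # the open-loop kinematics all poses are known before the run
            onset_pose = pose_worm(mesh, registry, spec.worm.state_at(ev.onset))
            idx = _window_steps(times, ev.onset, ev.onset + float(ev.duration))
            series = electro_photo.light_stimuli(
                lspec, onset_pose, registry, times[idx])
            for neuron, values in series.items():
                rows.add_series(times[idx], neuron, "photo", "", values)

    # --- phase 2: runtime stimuli ----------------------------------------
    static_fields = [
        _static_chem_field(ev, spec.plate_diameter)
        for ev in runtime
        if ev.kind in {"quadrants", "osmotic_ring", "chem_point_source"}
    ]
    drops = [ev for ev in runtime if ev.kind == "chem_drop"]
    thermal_fields = [
        _thermal_field(ev, spec.plate_diameter)
        for ev in runtime
        if ev.kind in {"thermal_gradient", "heat_point"}
    ]
    proprio_ev = next(
        (ev for ev in runtime if ev.kind == "proprioception"), None)
    do_curv = proprio_ev is not None and proprio_ev.get("curvature", "on") == "on"
    do_stretch = proprio_ev is not None and proprio_ev.get("stretch", "on") == "on"

    needs_loop = bool(static_fields or drops or thermal_fields
                      or spec.obstacles or do_curv or do_stretch)
    if needs_loop:
        for i, t in enumerate(times):
            state = pose_worm(mesh, registry, spec.worm.state_at(float(t)))
            entries: list[tuple[str, str, str, float]] = []

            fields = list(static_fields)
            for ev in drops:
                if t >= ev.onset:
                    center = (float(ev.get("x")), float(ev.get("y")))

                    def drop_field(pts, _ev=ev, _c=center, _t=float(t) - ev.onset):
                        return chemo.drop_concentration(
                            _c, float(_ev.get("amount")),
                            float(_ev.get("radius", 0.25)),
                            float(_ev.get("D", 1e-4)), _t, pts)

                    drop_field.substance = str(ev.get("substance"))
                    fields.append(drop_field)
            if fields:
                for (neuron, sub), val in chemo.chemo_stimuli(
                        fields, state, registry).items():
                    entries.append((neuron, "chemo", sub, val))

            for tf in thermal_fields:
                for neuron, val in thermo.thermo_stimuli(
                        tf, state, registry).items():
                    entries.append((neuron, "thermo", "", val))

            if do_curv:
                kappa = proprio.centerline_curvature(state.centerline)
                for neuron, val in proprio.curvature_stimuli(
                        kappa, registry, state).items():
                    entries.append((neuron, "proprio_curvature", "", val))
            if do_stretch:
                for neuron, val in proprio.muscle_stretch_stimuli(
                        state, registry).items():
                    entries.append((neuron, "proprio_stretch", "", val))

            for obstacle in spec.obstacles:
                contact = _obstacle_contact(obstacle, state.cuticle_world)
                if contact is None:
                    continue
                point, force = contact
                for neuron, val in mechano.collision_stimulus(
                        point, force, state, registry).items():
                    entries.append((neuron, "mechano", "", val))

            rows.add_step(float(t), entries)

    return rows.frame()


def write_table(table: pd.DataFrame, path: str, format: str = "long") -> None:
    """Write the stimulus table as CSV.

    ``long``: columns ``t,neuron,modality,channel,value`` sorted by
    ``(t, neuron, modality, channel)``.  ``wide``: one row per timestep, one
    column per ``neuron|modality|channel`` triple.
    """
    if format == "long":
        out = table.sort_values(["t", "neuron", "modality", "channel"],
                                ignore_index=True)
        out.to_csv(path, index=False)
    elif format == "wide":
        if table.empty:
            pd.DataFrame({"t": []}).to_csv(path, index=False)
            return
        key = (table["neuron"].astype(str) + "|" + table["modality"].astype(str)
               + "|" + table["channel"].astype(str))
        wide = table.assign(series=key).pivot_table(
            index="t", columns="series", values="value", aggfunc="sum",
            fill_value=0.0)
        wide = wide.reindex(sorted(wide.columns), axis=1)
        wide.to_csv(path)
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str) -> pd.DataFrame:
    """Read back a long-form stimulus CSV."""
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"neuron": str, "modality": str, "channel": str})
    df["t"] = df["t"].astype(float)
    df["value"] = df["value"].astype(float)
    return df
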