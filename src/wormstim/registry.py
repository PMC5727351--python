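"""Neuron, sensilla, muscle and neuromuscular-connectivity registries.

The default registry instantiates all 302 hermaphrodite neurons with
body-relative soma positions, routes sensilla to their member neurons
(amphids, labial, cephalic, deirid, phasmid sensilla), gives the six touch
receptor neurons (ALML/R, AVM, PLML/R, PVM) their long mechanosensory
processes, and builds 95 body-wall muscles in 8 longitudinal bundles with a
synthetic neuromuscular table in which the 75 ventral-cord motor neurons
innervate the 79 muscles posterior to the head.

Everything is user-overridable from CSV tables (see ``load_registry_csv`` /
``load_connectivity_csv``); the defaults are declared approximations of the
WormAtlas anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _neuron_table as nt
from .geometry import BodyMesh, build_body_mesh, reference_points

__all__ = [
    "RegistryError",
    "NeuronRecord",
    "SensillumRecord",
    "MuscleRecord",
    "Registry",
    "MODALITIES",
    "build_default_registry",
    "load_registry_csv",
    "load_connectivity_csv",
]

MODALITIES = frozenset({
    "mechano", "chemo", "thermo", "galvano", "photo",
    "proprio_curvature", "proprio_stretch",
})

ARBOR_RULES = ("point", "min_over_arbor", "max_over_arbor")

MUSCLE_BUNDLES = ("DLM", "DLL", "DRM", "DRL", "VLM", "VLL", "VRM", "VRL")
_BUNDLE_PHI = {
    "DLM": 25.0, "DLL": 50.0, "DRM": 335.0, "DRL": 310.0,
    "VLM": 155.0, "VLL": 130.0, "VRM": 205.0, "VRL": 230.0,
}
_BUNDLE_COUNT = {b: (11 if b == "VLL" else 12) for b in MUSCLE_BUNDLES}
_HEAD_MUSCLES_PER_BUNDLE = 2  # 16 head muscles; the remaining 79 are posterior
MUSCLE_NODES = 24


class RegistryError(ValueError):
    """Raised when a registry table violates its invariants."""


@dataclass(frozen=True)
class NeuronRecord:
    name: str
    u_soma: float
    phi_soma: float
    r_frac: float
    process: tuple[tuple[float, float, float], ...] = ()
    modalities: frozenset[str] = frozenset()
    sensilla: frozenset[str] = frozenset()
    arbor_rule: str = "point"


@dataclass(frozen=True)
class SensillumRecord:
    name: str
    u: float
    phi: float
    r_frac: float
    members: tuple[str, ...]


@dataclass(frozen=True)
class MuscleRecord:
    name: str
    bundle: str
    u_span: tuple[float, float]
    nodes: np.ndarray  # (24, 3) body-relative (u, phi, r_frac)
    rest_length: float  # mm, straight-pose polyline length
    is_head: bool


@dataclass
class Registry:
    """Complete anatomical routing table of the virtual worm."""

    neurons: dict[str, NeuronRecord]
    sensilla: dict[str, SensillumRecord]
    muscles: dict[str, MuscleRecord]
    connectivity: pd.DataFrame  # columns: neuron, muscle, weight
    arbors: dict[str, np.ndarray] = field(default_factory=dict)
    axons: dict[str, np.ndarray] = field(default_factory=dict)

    def neurons_with_modality(self, modality: str) -> list[str]:
        return [n for n, r in self.neurons.items() if modality in r.modalities]

    def neuron_geometry(self, name: str) -> np.ndarray:
        """Body-relative (u, phi, r_frac) points: soma followed by process."""
        rec = self.neurons[name]
        soma = np.array([[rec.u_soma, rec.phi_soma, rec.r_frac]])
        if rec.process:
            return np.vstack([soma, np.asarray(rec.process, dtype=float)])
        return soma

    def validate(self) -> None:
        for name, rec in self.neurons.items():
            _check_coords(name, rec.u_soma, rec.phi_soma, rec.r_frac)
            if rec.arbor_rule not in ARBOR_RULES:
                raise RegistryError(
                    f"neuron {name!r}: unknown arbor_rule {rec.arbor_rule!r}")
            unknown = rec.modalities - MODALITIES
            if unknown:
                raise RegistryError(
                    f"neuron {name!r}: unknown modalities {sorted(unknown)}")
            for u, phi, r in rec.process:
                _check_coords(f"{name} process", u, phi, r)
        for name, sens in self.sensilla.items():
            _check_coords(name, sens.u, sens.phi, sens.r_frac)
            for member in sens.members:
                if member not in self.neurons:
                    raise RegistryError(
                        f"sensillum {name!r}: member {member!r} is not a "
                        f"registered neuron")
        for name, mus in self.muscles.items():
            if mus.u_span[0] >= mus.u_span[1]:
                raise RegistryError(f"muscle {name!r}: u_span must be ordered")
            if mus.rest_length <= 0:
                raise RegistryError(f"muscle {name!r}: rest_length must be > 0")
        conn = self.connectivity
        for i, row in enumerate(conn.itertuples(index=False)):
            if row.neuron not in self.neurons:
                raise RegistryError(
                    f"connectivity row {i}: unknown neuron {row.neuron!r}")
            if row.muscle not in self.muscles:
                raise RegistryError(
                    f"connectivity row {i}: unknown muscle {row.muscle!r}")
            if int(row.weight) < 1:
                raise RegistryError(
                    f"connectivity row {i}: weight must be >= 1")


def _check_coords(label: str, u: float, phi: float, r: float) -> None:
    if not (0.0 <= u <= 1.0):
        raise RegistryError(f"{label}: u={u} outside [0, 1]")
    if not (0.0 <= phi < 360.0):
        raise RegistryError(f"{label}: phi={phi} outside [0, 360)")
    if not (0.0 <= r <= 1.0):
        raise RegistryError(f"{label}: r_frac={r} outside [0, 1]")


# ---------------------------------------------------------------------------
# default build
# ---------------------------------------------------------------------------

def _default_neuron_records(process_points: int) -> dict[str, NeuronRecord]:
    sensilla = nt.default_sensilla()
    member_to_sensilla: dict[str, set[str]] = {}
    for sname, (_, _, _, members) in sensilla.items():
        for m in members:
            member_to_sensilla.setdefault(m, set()).add(sname)

    head_classes = sorted(
        c for c in nt.PAIRED_CLASSES
        if c not in nt.CLASS_U and c not in nt.PHARYNGEAL
    )
    head_rank = {c: i for i, c in enumerate(head_classes)}
    phar_sorted = sorted(nt.PHARYNGEAL)

    records: dict[str, NeuronRecord] = {}

    def add(name: str, cls: str, u: float, phi: float, r: float = 0.6) -> None:
        phi = phi % 360.0
        r = nt.CLASS_RFRAC.get(cls, r)
        modalities = {"galvano", "photo"}
        if cls in nt.MECHANO_CLASSES or name in nt.MECHANO_SINGLES:
            modalities.add("mechano")
        if cls in nt.THERMO_CLASSES:
            modalities.add("thermo")
        if cls in nt.CURVATURE_CLASSES or name in nt.CURVATURE_SINGLES:
            modalities.add("proprio_curvature")
        if cls in nt.STRETCH_CLASSES:
            modalities.add("proprio_stretch")
        if name in member_to_sensilla:
            modalities.add("chemo")
        process: tuple = ()
        if name in nt.TOUCH_PROCESSES:
            u0, u1, pphi, pr = nt.TOUCH_PROCESSES[name]
            us = np.linspace(u0, u1, process_points)
            process = tuple((float(x), pphi, pr) for x in us)
        arbor_rule = "point"
        if cls == "PVD":
            arbor_rule = "min_over_arbor"
        elif cls == "FLP":
            arbor_rule = "max_over_arbor"
        records[name] = NeuronRecord(
            name=name,
            u_soma=float(u),
            phi_soma=float(phi),
            r_frac=float(r),
            process=process,
            modalities=frozenset(modalities),
            sensilla=frozenset(member_to_sensilla.get(name, ())),
            arbor_rule=arbor_rule,
        )

    for cls in nt.PAIRED_CLASSES:
        if cls in nt.CLASS_U:
            u = nt.CLASS_U[cls]
        elif cls in nt.PHARYNGEAL:
            u = 0.03 + 0.05 * phar_sorted.index(cls) / max(len(phar_sorted) - 1, 1)
        else:
            u = nt.head_u(cls, head_rank[cls], len(head_classes))
        if cls in nt.CLASS_PHI:
            phi_l = nt.CLASS_PHI[cls]
        elif cls in nt.DORSAL_SUBCLASSES:
            phi_l = 45.0
        elif cls in nt.VENTRAL_SUBCLASSES:
            phi_l = 135.0
        else:
            phi_l = 90.0
        add(cls + "L", cls, u, phi_l)
        add(cls + "R", cls, u, (360.0 - phi_l) % 360.0)

    phar_singles = sorted(n for n in nt.UNPAIRED if n in nt.PHARYNGEAL)
    for name in nt.UNPAIRED:
        if name in nt.CLASS_U:
            u = nt.CLASS_U[name]
        elif name in nt.PHARYNGEAL:
            u = 0.035 + 0.04 * phar_singles.index(name) / max(len(phar_singles) - 1, 1)
        else:
            u = 0.10
        phi = nt.SINGLE_PHI.get(name, 0.0)
        add(name, name, u, phi)

    for cls, n in nt.MOTOR_CLASSES.items():
        for i in range(1, n + 1):
            add(f"{cls}{i}", cls, nt.motor_u(cls, i), 180.0)

    return records


def _default_muscles(mesh: BodyMesh) -> dict[str, MuscleRecord]:
    muscles: dict[str, MuscleRecord] = {}
    for bundle in MUSCLE_BUNDLES:
        n = _BUNDLE_COUNT[bundle]
        phi = _BUNDLE_PHI[bundle]
        bounds = np.linspace(0.03, 0.97, n + 1)
        for i in range(n):
            u0, u1 = float(bounds[i]), float(bounds[i + 1])
            us = np.linspace(u0, u1, MUSCLE_NODES)
            nodes = np.column_stack([
                us, np.full(MUSCLE_NODES, phi), np.full(MUSCLE_NODES, 0.8)])
            ref = reference_points(mesh, nodes[:, 0], nodes[:, 1], nodes[:, 2])
            rest = float(np.linalg.norm(np.diff(ref, axis=0), axis=1).sum())
            name = f"{bundle}{i + 1:02d}"
            muscles[name] = MuscleRecord(
                name=name,
                bundle=bundle,
                u_span=(u0, u1),
                nodes=nodes,
                rest_length=rest,
                is_head=i < _HEAD_MUSCLES_PER_BUNDLE,
            )
    return muscles


def _default_connectivity(
    neurons: dict[str, NeuronRecord],
    muscles: dict[str, MuscleRecord],
) -> pd.DataFrame:
    """Synthetic neuromuscular table: 75 VNC motor neurons x 79 posterior
    muscles, each neuron wired to the muscles overlapping its axial
    neighborhood in its dorsal/ventral bundles."""
    dorsal = [b for b in MUSCLE_BUNDLES if b.startswith("D")]
    ventral = [b for b in MUSCLE_BUNDLES if b.startswith("V")]
    class_bundles = {
        "AS": dorsal, "DA": dorsal, "DB": dorsal, "DD": dorsal,
        "VA": ventral, "VB": ventral, "VC": ventral, "VD": ventral,
    }
    posterior = [m for m in muscles.values() if not m.is_head]

    rows: list[tuple[str, str, int]] = []
    for cls, n in nt.MOTOR_CLASSES.items():
        for i in range(1, n + 1):
            name = f"{cls}{i}"
            u = neurons[name].u_soma
            lo, hi = u - 0.07, u + 0.07
            for mus in posterior:
                if mus.bundle not in class_bundles[cls]:
                    continue
                if mus.u_span[1] < lo or mus.u_span[0] > hi:
                    continue
                center = 0.5 * (mus.u_span[0] + mus.u_span[1])
                weight = 2 if abs(center - u) <= 0.04 else 1
                rows.append((name, mus.name, weight))

    covered = {m for _, m, _ in rows}
    for mus in posterior:
        if mus.name in covered:
            continue
        center = 0.5 * (mus.u_span[0] + mus.u_span[1])
        wanted = {b for b, bl in class_bundles.items() if mus.bundle in bl}
        best = min(
            (nm for nm, r in neurons.items()
             if "proprio_stretch" in r.modalities
             and _motor_class(nm) in wanted),
            key=lambda nm: abs(neurons[nm].u_soma - center),
        )
        rows.append((best, mus.name, 1))

    df = pd.DataFrame(rows, columns=["neuron", "muscle", "weight"])
    return df.sort_values(["neuron", "muscle"], ignore_index=True)


def _motor_class(name: str) -> str:
    return name.rstrip("0123456789")


def build_default_registry(
    overrides: pd.DataFrame | str | None = None,
    connectivity: pd.DataFrame | str | None = None,
    mesh: BodyMesh | None = None,
    process_points: int = 20,
    arbor_points: int = 40,
) -> Registry:
    """Build the default 302-neuron registry, optionally patched from CSVs.

    ``overrides`` rows replace (or add) neuron records by name; a duplicate
    name inside the override table is a validation error.  ``connectivity``
    replaces the synthetic neuromuscular table entirely.
    """
    mesh = mesh or build_body_mesh()
    neurons = _default_neuron_records(process_points)
    if overrides is not None:
        if isinstance(overrides, str):
            overrides = pd.read_csv(overrides)
        _apply_overrides(neurons, overrides)

    sens_table = nt.default_sensilla()
    sensilla = {
        name: SensillumRecord(name, u, phi, r, tuple(members))
        for name, (u, phi, r, members) in sens_table.items()
    }
    muscles = _default_muscles(mesh)
    if connectivity is None:
        conn = _default_connectivity(neurons, muscles)
    else:
        if isinstance(connectivity, str):
            connectivity = load_connectivity_csv(connectivity)
        conn = connectivity.reset_index(drop=True)

    arbors: dict[str, np.ndarray] = {}
    for name, rec in neurons.items():
        if rec.arbor_rule != "point":
            # the dendritic tree spans most of the body and is rooted at the
            # soma, so the span always includes the soma's axial position
            us = np.linspace(min(0.1, rec.u_soma), max(0.9, rec.u_soma),
                             arbor_points)
            arbors[name] = np.column_stack([
                us, np.full(arbor_points, rec.phi_soma),
                np.full(arbor_points, 0.9)])

    axons: dict[str, np.ndarray] = {}
    for name, rec in neurons.items():
        cls = _motor_class(name)
        if cls in {"AS", "DA", "DB", "VA", "VB"} and name in neurons:
            u0 = max(rec.u_soma - 0.06, 0.02)
            u1 = min(rec.u_soma + 0.06, 0.98)
            us = np.linspace(u0, u1, 7)
            axons[name] = np.column_stack([
                us, np.full(7, rec.phi_soma), np.full(7, rec.r_frac)])

    registry = Registry(
        neurons=neurons,
        sensilla=sensilla,
        muscles=muscles,
        connectivity=conn,
        arbors=arbors,
        axons=axons,
    )
    registry.validate()
    return registry


def _apply_overrides(neurons: dict[str, NeuronRecord], table: pd.DataFrame) -> None:
    required = {"name", "u_soma", "phi_soma", "r_frac"}
    missing = required - set(table.columns)
    if missing:
        raise RegistryError(f"override table missing columns {sorted(missing)}")
    seen: set[str] = set()
    for i, row in enumerate(table.to_dict("records")):
        name = str(row["name"])
        if name in seen:
            raise RegistryError(f"override row {i}: duplicate neuron name {name!r}")
        seen.add(name)
        base = neurons.get(name)
        modalities = (
            frozenset(_split(row.get("modalities")))
            if _present(row.get("modalities"))
            else (base.modalities if base else frozenset({"galvano", "photo"}))
        )
        sensilla = (
            frozenset(_split(row.get("sensilla")))
            if _present(row.get("sensilla"))
            else (base.sensilla if base else frozenset())
        )
        arbor_rule = (
            str(row["arbor_rule"]) if _present(row.get("arbor_rule"))
            else (base.arbor_rule if base else "point")
        )
        process: tuple = base.process if base else ()
        if _present(row.get("process")):
            process = tuple(
                tuple(float(x) for x in triple.split(":"))
                for triple in str(row["process"]).split(";")
                if triple.strip()
            )
        neurons[name] = NeuronRecord(
            name=name,
            u_soma=float(row["u_soma"]),
            phi_soma=float(row["phi_soma"]) % 360.0,
            r_frac=float(row["r_frac"]),
            process=process,
            modalities=modalities,
            sensilla=sensilla,
            arbor_rule=arbor_rule,
        )


def _present(value) -> bool:
    return value is not None and not (isinstance(value, float) and np.isnan(value)) \
        and str(value).strip() != ""


def _split(value) -> list[str]:
    return [tok.strip() for tok in str(value).split("|") if tok.strip()]


def load_registry_csv(path: str) -> pd.DataFrame:
    """Read a registry override CSV (columns: name,u_soma,phi_soma,r_frac,
    modalities,sensilla,arbor_rule,process)."""
    return pd.read_csv(path)


def load_connectivity_csv(path: str) -> pd.DataFrame:
    """Read a neuromuscular connectivity CSV (columns: neuron,muscle,weight)."""
    df = pd.read_csv(path)
    missing = {"neuron", "muscle", "weight"} - set(df.columns)
    if missing:
        raise RegistryError(f"connectivity table missing columns {sorted(missing)}")
    return df
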