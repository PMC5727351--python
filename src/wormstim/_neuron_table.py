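"""Canonical hermaphrodite neuron list and default body-relative placements.

The 302 neurons are generated from the standard class decomposition:
99 left/right pairs, 29 unpaired neurons (including the 20 pharyngeal ones)
and 75 ventral-cord motor neurons (AS, DA, DB, DD, VA, VB, VC, VD).

Soma coordinates are coarse, literature-informed placements expressed in the
package's body frame (axial u in [0,1] nose->tail; angular phi in degrees with
0 = dorsal midline, 90 = left, 180 = ventral, 270 = right; radial position as
a fraction of the local body radius).  They are configuration, not ground
truth, and can be overridden from a CSV table.
"""

from __future__ import annotations

# 99 classes instantiated as <class>L / <class>R
PAIRED_CLASSES = [
    "ADA", "ADE", "ADF", "ADL", "AFD", "AIA", "AIB", "AIM", "AIN", "AIY",
    "AIZ", "ALM", "ALN", "ASE", "ASG", "ASH", "ASI", "ASJ", "ASK", "AUA",
    "AVA", "AVB", "AVD", "AVE", "AVF", "AVH", "AVJ", "AVK", "AWA", "AWB",
    "AWC", "BAG", "BDU", "CAN", "CEPD", "CEPV", "FLP", "HSN", "IL1", "IL1D",
    "IL1V", "IL2", "IL2D", "IL2V", "LUA", "OLL", "OLQD", "OLQV", "PDE",
    "PHA", "PHB", "PHC", "PLM", "PLN", "PVC", "PVD", "PVN", "PVP", "PVQ",
    "PVW", "RIA", "RIB", "RIC", "RIF", "RIG", "RIM", "RIP", "RIV", "RMD",
    "RMDD", "RMDV", "RME", "RMF", "RMG", "RMH", "SAAD", "SAAV", "SABV",
    "SDQ", "SIAD", "SIAV", "SIBD", "SIBV", "SMBD", "SMBV", "SMDD", "SMDV",
    "URAD", "URAV", "URB", "URX", "URYD", "URYV",
    # pharyngeal pairs
    "I1", "I2", "M2", "M3", "MC", "NSM",
]

UNPAIRED = [
    "ALA", "AQR", "AVG", "AVL", "AVM", "DVA", "DVB", "DVC",
    "I3", "I4", "I5", "I6", "M1", "M4", "M5", "MI",
    "PDA", "PDB", "PQR", "PVM", "PVR", "PVT",
    "RID", "RIH", "RIR", "RIS", "RMED", "RMEV", "SABD",
]

# ventral nerve cord motor neuron classes and member counts
MOTOR_CLASSES = {
    "AS": 11, "DA": 9, "DB": 7, "DD": 6,
    "VA": 12, "VB": 11, "VC": 6, "VD": 13,
}

PHARYNGEAL = {
    "I1", "I2", "I3", "I4", "I5", "I6",
    "M1", "M2", "M3", "M4", "M5", "MC", "MI", "NSM",
}

# classes whose members sit on the dorsal / ventral sub-lateral lines
DORSAL_SUBCLASSES = {
    "CEPD", "IL1D", "IL2D", "OLQD", "RMDD", "SAAD", "SIAD", "SIBD",
    "SMBD", "SMDD", "URAD", "URYD",
}
VENTRAL_SUBCLASSES = {
    "CEPV", "IL1V", "IL2V", "OLQV", "RMDV", "SAAV", "SIAV", "SIBV",
    "SMBV", "SMDV", "URAV", "URYV",
}

# explicit axial soma positions for classes outside the head ganglia
CLASS_U = {
    "ALM": 0.42, "AVM": 0.33, "PVM": 0.58, "PLM": 0.91,
    "BDU": 0.12, "FLP": 0.08, "PVD": 0.72, "PDE": 0.62,
    "CAN": 0.45, "HSN": 0.55, "SDQ": 0.50, "ALN": 0.88, "PLN": 0.90,
    "SABV": 0.20, "SABD": 0.20,
    "AQR": 0.10, "PQR": 0.93,
    "LUA": 0.92, "PHA": 0.94, "PHB": 0.95, "PHC": 0.96,
    "PVC": 0.90, "PVN": 0.92, "PVP": 0.89, "PVQ": 0.91, "PVR": 0.95,
    "PVT": 0.88, "PVW": 0.93, "PDA": 0.88, "PDB": 0.89,
    "DVA": 0.92, "DVB": 0.93, "DVC": 0.94,
}

# classes placed in the tail even though not listed above
TAIL_CLASSES = set(CLASS_U) - {
    "ALM", "AVM", "BDU", "FLP", "CAN", "HSN", "SDQ", "SABV", "SABD", "AQR",
}

# soma radial placement overrides (fraction of local radius); lateral-cord
# neurons sit close to the body wall
CLASS_RFRAC = {"BDU": 0.8, "ALM": 0.8, "PLM": 0.8, "CAN": 0.8, "SDQ": 0.8}

# explicit phi (left member; right member mirrors to 360 - phi)
CLASS_PHI = {
    "ALM": 100.0, "PLM": 100.0, "PVD": 90.0, "FLP": 90.0, "BDU": 90.0,
    "CAN": 90.0, "HSN": 160.0, "SDQ": 90.0, "ALN": 80.0, "PLN": 100.0,
    "LUA": 150.0, "PHA": 160.0, "PHB": 160.0, "PHC": 150.0,
}

SINGLE_PHI = {
    "AVM": 215.0, "PVM": 145.0, "RMED": 0.0, "RMEV": 180.0,
    "ALA": 0.0, "RID": 0.0, "AVG": 180.0, "AVL": 180.0,
    "DVA": 180.0, "DVB": 180.0, "DVC": 180.0,
    "PDA": 0.0, "PDB": 180.0, "PQR": 180.0, "AQR": 90.0,
    "PVM": 145.0, "PVR": 180.0, "PVT": 180.0,
    "SABD": 0.0, "RIH": 180.0, "RIR": 90.0, "RIS": 180.0,
    "MI": 0.0,
}

# default mechanosensory process polylines for the six touch receptor
# neurons: (u_start, u_end, phi, r_frac); left members listed, right members
# mirror phi.  Spans follow the described sensation regions: ALM/AVM anterior
# half, PVM mid-body, PLM posterior part.
TOUCH_PROCESSES = {
    "ALML": (0.05, 0.45, 100.0, 0.9),
    "ALMR": (0.05, 0.45, 260.0, 0.9),
    "AVM": (0.05, 0.50, 215.0, 0.9),
    "PVM": (0.30, 0.65, 145.0, 0.9),
    "PLML": (0.55, 0.95, 100.0, 0.9),
    "PLMR": (0.55, 0.95, 260.0, 0.9),
}

# modality membership by class
MECHANO_CLASSES = {
    "ALM", "PLM", "ASH", "OLQD", "OLQV", "IL1", "IL1D", "IL1V",
    "CEPD", "CEPV", "ADE", "PDE", "FLP", "PVD", "BDU", "LUA",
}
MECHANO_SINGLES = {"AVM", "PVM"}
THERMO_CLASSES = {"AFD", "AWC", "PVD", "FLP", "BDU", "CEPD", "CEPV", "PHB", "PHC"}
CURVATURE_CLASSES = {"ALM", "PLM", "AS", "DA", "DB", "VA", "VB"}
CURVATURE_SINGLES = {"AVM", "PVM"}
STRETCH_CLASSES = set(MOTOR_CLASSES)

# sensilla: name -> (u, phi, r_frac, member neuron names)
AMPHID_MEMBER_CLASSES = [
    "ADF", "ADL", "AFD", "ASE", "ASG", "ASH", "ASI", "ASJ", "ASK",
    "AWA", "AWB", "AWC",
]


def _mirror(phi: float) -> float:
    return (360.0 - phi) % 360.0


def default_sensilla() -> dict[str, tuple[float, float, float, list[str]]]:
    """20 head sensilla plus 3 posterior pairs with WormAtlas-style wiring.

    The third posterior pair ("caudal", housing PHC) is a declared
    approximation; phasmids and postdeirids are standard.
    """
    sens: dict[str, tuple[float, float, float, list[str]]] = {}
    for side, phi_sign in (("L", 1.0), ("R", -1.0)):
        def ph(p: float) -> float:
            return p % 360.0 if phi_sign > 0 else _mirror(p)

        sens[f"amphid_{side}"] = (
            0.02, ph(90.0), 1.0, [c + side for c in AMPHID_MEMBER_CLASSES])
        sens[f"inner_labial_dorsal_{side}"] = (
            0.010, ph(30.0), 1.0, [f"IL1D{side}", f"IL2D{side}"])
        sens[f"inner_labial_lateral_{side}"] = (
            0.010, ph(90.0), 1.0, [f"IL1{side}", f"IL2{side}"])
        sens[f"inner_labial_ventral_{side}"] = (
            0.010, ph(150.0), 1.0, [f"IL1V{side}", f"IL2V{side}"])
        sens[f"outer_labial_dorsal_{side}"] = (
            0.015, ph(45.0), 1.0, [f"OLQD{side}"])
        sens[f"outer_labial_lateral_{side}"] = (
            0.015, ph(90.0), 1.0, [f"OLL{side}"])
        sens[f"outer_labial_ventral_{side}"] = (
            0.015, ph(135.0), 1.0, [f"OLQV{side}"])
        sens[f"cephalic_dorsal_{side}"] = (
            0.03, ph(40.0), 1.0, [f"CEPD{side}"])
        sens[f"cephalic_ventral_{side}"] = (
            0.03, ph(140.0), 1.0, [f"CEPV{side}"])
        sens[f"deirid_{side}"] = (0.18, ph(90.0), 1.0, [f"ADE{side}"])
        sens[f"postdeirid_{side}"] = (0.62, ph(90.0), 1.0, [f"PDE{side}"])
        sens[f"phasmid_{side}"] = (
            0.93, ph(140.0), 1.0, [f"PHA{side}", f"PHB{side}"])
        sens[f"caudal_{side}"] = (0.97, ph(140.0), 1.0, [f"PHC{side}"])
    return sens


def all_neuron_names() -> list[str]:
    names: list[str] = []
    for cls in PAIRED_CLASSES:
        names.append(cls + "L")
        names.append(cls + "R")
    names.extend(UNPAIRED)
    for cls, n in MOTOR_CLASSES.items():
        names.extend(f"{cls}{i}" for i in range(1, n + 1))
    return names


def motor_u(cls: str, index: int) -> float:
    """Axial soma position of ventral-cord motor neuron <cls><index>."""
    n = MOTOR_CLASSES[cls]
    if n == 1:
        return 0.55
    return 0.25 + 0.65 * (index - 1) / (n - 1)


def head_u(cls: str, rank: int, n_head: int) -> float:
    """Deterministic spread of head-ganglion classes over u in [0.06, 0.16]."""
    if n_head <= 1:
        return 0.10
    return 0.06 + 0.10 * rank / (n_head - 1)
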