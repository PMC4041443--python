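"""Idealized monomer template geometries.

Planar aromatic side chains and nucleobases are built from (fused)
regular polygons with a 1.39 A ring bond; the deoxyribose is built from
internal coordinates with a C2'-endo pucker (pseudorotation phase 162
degrees, amplitude 35 degrees) and B-DNA-like exocyclic torsions.

These templates exist to exercise the survey classifiers with fully
known ground truth; they are deliberately idealized, not crystal-accurate.
All templates are heavy-atom only (plus the glycosidic nitrogen stub on
the sugar) so that fixtures look like real 2.0 A crystal structures,
which lack hydrogens.
"""

from __future__ import annotations

import numpy as np

from .geometry import TETRAHEDRAL_ANGLE, place_atom, rotation_about_axis

__all__ = [
    "aromatic_template",
    "nucleobase_template",
    "deoxyribose_template",
    "AROMATIC_RESIDUES",
    "NUCLEOBASE_RESIDUES",
]

RING_BOND = 1.39
AROMATIC_RESIDUES = ("PHE", "TYR", "HIS", "TRP")
NUCLEOBASE_RESIDUES = ("DA", "DC", "DG", "DT")

# exocyclic bond lengths, A
_B_CO = 1.23   # carbonyl
_B_CN = 1.34   # ring C - amino N
_B_CC = 1.50   # ring C - methyl C
_B_NC1 = 1.47  # glycosidic N - C1'
_B_CCB = 1.51  # ring C - CB


def _regular_polygon(n: int, bond: float = RING_BOND) -> np.ndarray:
    r = bond / (2.0 * np.sin(np.pi / n))
    ang = np.radians(90.0 + 360.0 * np.arange(n) / n)
    return np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)], axis=1)


def _attach_polygon(a: np.ndarray, b: np.ndarray, n: int,
                    away_from: np.ndarray) -> list[np.ndarray]:
    """Regular n-gon sharing edge a-b, on the opposite side from ``away_from``.

    Returns the n-2 new vertices in cycle order a -> v1 -> ... -> b.
    """
    mid = (a + b) / 2.0
    edge = b - a
    bond = np.linalg.norm(edge)
    apothem = bond / (2.0 * np.tan(np.pi / n))
    perp = np.cross([0.0, 0.0, 1.0], edge)
    perp /= np.linalg.norm(perp)
    if np.dot(perp, away_from - mid) > 0:
        perp = -perp
    center = mid + apothem * perp
    step = 2.0 * np.pi / n
    # choose rotation sense so the first step from a does not land on b
    for sign in (1.0, -1.0):
        rot = rotation_about_axis([0, 0, 1], np.degrees(sign * step))
        first = center + rot @ (a - center)
        if np.linalg.norm(first - b) > 1e-6:
            verts = []
            p = a
            for _ in range(n - 2):
                p = center + rot @ (p - center)
                verts.append(p.copy())
            return verts
    raise RuntimeError("degenerate polygon attachment")


def _exocyclic(atoms: dict, ring_atom: str, n1: str, n2: str,
               bond: float) -> np.ndarray:
    """Place a substituent on ``ring_atom`` along the external bisector."""
    r = atoms[ring_atom]
    u1 = atoms[n1] - r
    u2 = atoms[n2] - r
    d = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
    return r + bond * d / np.linalg.norm(d)


def aromatic_template(residue_name: str) -> dict[str, np.ndarray]:
    """Heavy atoms of one aromatic side chain, ring in the z=0 plane.

    Includes CB (the backbone link stub) and, for Tyr, OH.
    """
    resname = residue_name.upper()
    atoms: dict[str, np.ndarray] = {}
    if resname in ("PHE", "TYR"):
        cycle = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        pts = _regular_polygon(6)
        atoms = dict(zip(cycle, pts))
        atoms["CB"] = _exocyclic(atoms, "CG", "CD1", "CD2", _B_CCB)
        if resname == "TYR":
            atoms["OH"] = _exocyclic(atoms, "CZ", "CE1", "CE2", 1.36)
    elif resname == "HIS":
        cycle = ("CG", "ND1", "CE1", "NE2", "CD2")
        pts = _regular_polygon(5)
        atoms = dict(zip(cycle, pts))
        atoms["CB"] = _exocyclic(atoms, "CG", "ND1", "CD2", _B_CCB)
    elif resname == "TRP":
        cycle = ("CG", "CD1", "NE1", "CE2", "CD2")
        pts = _regular_polygon(5)
        atoms = dict(zip(cycle, pts))
        hexa = _attach_polygon(atoms["CE2"], atoms["CD2"], 6, atoms["CG"])
        for name, p in zip(("CZ2", "CH2", "CZ3", "CE3"), hexa):
            atoms[name] = p
        atoms["CB"] = _exocyclic(atoms, "CG", "CD1", "CD2", _B_CCB)
    else:
        raise KeyError(f"unknown aromatic residue {residue_name!r}")
    centroid = np.mean([atoms[n] for n in cycle], axis=0)
    return {k: v - centroid for k, v in atoms.items()}


def nucleobase_template(residue_name: str) -> dict[str, np.ndarray]:
    """Heavy atoms of one nucleobase, ring(s) in the z=0 plane.

    Includes the exocyclic substituents and a C1' stub marking the
    glycosidic direction.
    """
    resname = residue_name.upper()
    atoms: dict[str, np.ndarray] = {}
    if resname in ("DC", "DT"):
        cycle = ("N1", "C2", "N3", "C4", "C5", "C6")
        pts = _regular_polygon(6)
        atoms = dict(zip(cycle, pts))
        atoms["O2"] = _exocyclic(atoms, "C2", "N1", "N3", _B_CO)
        if resname == "DC":
            atoms["N4"] = _exocyclic(atoms, "C4", "N3", "C5", _B_CN)
        else:
            atoms["O4"] = _exocyclic(atoms, "C4", "N3", "C5", _B_CO)
            atoms["C7"] = _exocyclic(atoms, "C5", "C4", "C6", _B_CC)
        atoms["C1'"] = _exocyclic(atoms, "N1", "C2", "C6", _B_NC1)
        ring = cycle
    elif resname in ("DA", "DG"):
        hex_cycle = ("C4", "C5", "C6", "N1", "C2", "N3")
        pts = _regular_polygon(6)
        atoms = dict(zip(hex_cycle, pts))
        penta = _attach_polygon(atoms["C4"], atoms["C5"], 5, atoms["N1"])
        for name, p in zip(("N9", "C8", "N7"), penta):
            atoms[name] = p
        if resname == "DA":
            atoms["N6"] = _exocyclic(atoms, "C6", "C5", "N1", _B_CN)
        else:
            atoms["O6"] = _exocyclic(atoms, "C6", "C5", "N1", _B_CO)
            atoms["N2"] = _exocyclic(atoms, "C2", "N1", "N3", _B_CN)
        atoms["C1'"] = _exocyclic(atoms, "N9", "C8", "C4", _B_NC1)
        ring = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
    else:
        raise KeyError(f"unknown nucleobase residue {residue_name!r}")
    centroid = np.mean([atoms[n] for n in ring], axis=0)
    return {k: v - centroid for k, v in atoms.items()}


def _tetrahedral_slots(center, n1, n2):
    """The two free tetrahedral directions on an sp3 center with two
    known substituents; returned as unit vectors (slot_plus, slot_minus)
    where 'plus' has positive component along cross(u1, u2)."""
    u1 = (n1 - center) / np.linalg.norm(n1 - center)
    u2 = (n2 - center) / np.linalg.norm(n2 - center)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = np.radians(TETRAHEDRAL_ANGLE / 2.0)
    plus = np.cos(half) * bis + np.sin(half) * perp
    minus = np.cos(half) * bis - np.sin(half) * perp
    return plus, minus


def deoxyribose_template(glyco_name: str = "N1") -> dict[str, np.ndarray]:
    """Heavy atoms of a C2'-endo deoxyribose with B-DNA-like exocyclics.

    Returns C1'-C4', O4', C5', O5', O3' and a glycosidic-nitrogen stub
    (``glyco_name``, N1 for pyrimidines / N9 for purines).  The natural
    D-sugar chirality is used: the glycosidic nitrogen and C5' lie on the
    same face of the ring, O3' on the opposite face.
    """
    # C2'-endo pseudorotation; the construction below is reflected to the
    # D enantiomer at the end, so internal torsions are negated here
    amplitude, phase = 35.0, 162.0
    nu0 = -amplitude * np.cos(np.radians(phase - 288.0))
    nu1 = -amplitude * np.cos(np.radians(phase - 144.0))

    atoms: dict[str, np.ndarray] = {}
    atoms["C4'"] = np.zeros(3)
    atoms["O4'"] = np.array([1.446, 0.0, 0.0])
    # C1' in the z=0 plane at the ring O angle
    ang = np.radians(109.9)
    atoms["C1'"] = atoms["O4'"] + 1.42 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms["C2'"] = place_atom(atoms["C4'"], atoms["O4'"], atoms["C1'"],
                              1.52, 106.0, nu0)
    atoms["C3'"] = place_atom(atoms["O4'"], atoms["C1'"], atoms["C2'"],
                              1.53, 102.5, nu1)

    # ring-face normal (right-handed along C1'->C2'->C3')
    n = np.cross(atoms["C2'"] - atoms["C1'"], atoms["C3'"] - atoms["C2'"])
    n /= np.linalg.norm(n)

    def pick(center, nb1, nb2, want_positive):
        plus, minus = _tetrahedral_slots(atoms[center], atoms[nb1], atoms[nb2])
        cand = sorted([plus, minus], key=lambda v: float(np.dot(v, n)))
        return cand[1] if want_positive else cand[0]

    # C5' and the base nitrogen on the same (+n) face, O3' on the other
    atoms["C5'"] = atoms["C4'"] + 1.51 * pick("C4'", "C3'", "O4'", True)
    atoms[glyco_name] = atoms["C1'"] + _B_NC1 * pick("C1'", "O4'", "C2'", True)
    atoms["O3'"] = atoms["C3'"] + 1.42 * pick("C3'", "C2'", "C4'", False)
    # gamma torsion O5'-C5'-C4'-C3' ~ +54 deg (gauche+) after reflection
    atoms["O5'"] = place_atom(atoms["C3'"], atoms["C4'"], atoms["C5'"],
                              1.44, 110.5, -54.0)
    # reflect to the natural D enantiomer (checked against an embedded
    # thymidine: signs of the C1'/C4' chirality triple products)
    atoms = {k: v * np.array([1.0, 1.0, -1.0]) for k, v in atoms.items()}
    centroid = np.mean([atoms[nme] for nme in
                        ("C1'", "C2'", "C3'", "C4'", "O4'")], axis=0)
    return {k: v - centroid for k, v in atoms.items()}
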