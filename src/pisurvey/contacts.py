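"""Contact screening and classification — the survey's core procedure.

Candidate (aromatic ring, nucleobase) and (aromatic ring, deoxyribose)
pairs are screened at a heavy-atom distance cutoff (default 5.0 A).
Candidates are then validated with an explicit geometric surrogate for
expert visual inspection: a contact counts as a pi-interaction only if
enough atoms of one monomer sit above the other monomer's aromatic face
(within a perpendicular-height limit and a lateral buffer around the
ring polygon).  This rejects the classic false positive of two coplanar
rings that are merely close side by side.

pi-pi contacts are binned by interplanar tilt omega into stacked
[0, 20), inclined [20, 70) and T-shaped [70, 90] and, for non-stacked
geometries, assigned an edge role (which monomer presents its edge to
the other's face).  Sugar-pi contacts are classified by the five-edge
taxonomy — single proton, bridged (2 H), face (3 H), lone pair (O4'
only) and lone pair-proton — with the participating sugar atoms named
H1a, H2a, H2b, H3, H4, H5a, H5b and O4'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import MultiPoint, Point

from .geometry import (GeometryError, build_hydrogens, min_heavy_distance,
                       tilt_angle)
from .structure_io import Moiety, extract_moieties, read_structure

__all__ = [
    "ValidityCriteria",
    "Candidate",
    "PiPiContact",
    "SugarPiContact",
    "SUGAR_LABELS",
    "screen_candidates",
    "classify_tilt",
    "validate_pi_pi",
    "assign_edge_role",
    "classify_pi_pi",
    "label_sugar_atoms",
    "classify_sugar_contact",
    "survey_structure",
    "contacts_to_dataframe",
]

SUGAR_H_ORDER = ("H1a", "H2a", "H2b", "H3", "H4", "H5a", "H5b")
SUGAR_LABELS = ("O4'",) + SUGAR_H_ORDER
LABEL_SEPARATOR = "-"


@dataclass
class ValidityCriteria:
    """Thresholds of the visual-inspection surrogate.

    ``cutoff`` is the screening distance; the remaining fields quantify
    "atom sits over the aromatic face": perpendicular height above the
    best-fit ring plane, lateral offset beyond the convex ring polygon,
    and (for sugar C-H groups) the maximum angle between the X-H bond
    and the face normal, expressing C-H...pi directionality.
    """

    cutoff: float = 5.0
    max_perpendicular_height: float = 4.5
    max_lateral_offset: float = 1.5
    min_participating_atoms: int = 2
    sugar_max_height: float = 4.0
    sugar_max_offset: float = 1.5
    sugar_ch_angle_max: float = 60.0
    score_o3_o5_lone_pairs: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ValidityCriteria":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Candidate:
    aromatic: Moiety
    partner: Moiety  # nucleobase_ring or deoxyribose
    d_min: float

    @property
    def kind(self) -> str:
        return "pi_pi" if self.partner.kind == "nucleobase_ring" else "sugar_pi"


@dataclass
class PiPiContact:
    entry_id: str
    base_id: str
    aa_id: str
    base_resname: str
    aa_resname: str
    omega: float
    d_min: float
    category: str | None
    edge_role: str | None
    valid: bool
    reason: str = ""


@dataclass
class SugarPiContact:
    entry_id: str
    sugar_id: str
    aa_id: str
    sugar_resname: str
    aa_resname: str
    edge_class: str | None
    atom_labels: str
    d_min: float
    valid: bool
    reason: str = ""
    participation: dict = field(default_factory=dict)  # label -> (height, offset)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def screen_candidates(moieties: list[Moiety], cutoff: float = 5.0) -> list[Candidate]:
    """All (aromatic, base) and (aromatic, sugar) pairs with minimum
    heavy-atom distance strictly below ``cutoff``."""
    aromatics = [m for m in moieties if m.kind == "aromatic_aa_ring"]
    partners = [m for m in moieties if m.kind in ("nucleobase_ring", "deoxyribose")]
    out = []
    for aa in aromatics:
        pa = aa.heavy_points()
        for partner in partners:
            d = min_heavy_distance(pa, partner.heavy_points())
            if d < cutoff:
                out.append(Candidate(aromatic=aa, partner=partner, d_min=d))
    out.sort(key=lambda c: (c.aromatic.residue_id, c.partner.kind,
                            c.partner.residue_id))
    return out


def classify_tilt(omega: float) -> str:
    """Tilt category: [0,20) stacked, [20,70) inclined, [70,90] T-shaped."""
    if not 0.0 <= omega <= 90.0:
        raise ValueError(f"tilt angle {omega} outside [0, 90]")
    if omega < 20.0:
        return "stacked"
    if omega < 70.0:
        return "inclined"
    return "t_shaped"


def _face_frame(moiety: Moiety):
    """Ring plane, an in-plane orthonormal basis, and the convex ring
    polygon in plane coordinates."""
    plane = moiety.plane()
    n = plane.unit_normal
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    pts2d = [(float((p - plane.centroid) @ e1), float((p - plane.centroid) @ e2))
             for p in moiety.ring_points()]
    polygon = MultiPoint(pts2d).convex_hull
    return plane, e1, e2, polygon


def _participation(points, plane, e1, e2, polygon, max_height, max_offset):
    """(index, |height|, offset-beyond-polygon) for atoms over the face."""
    out = []
    for i, p in enumerate(np.atleast_2d(points)):
        rel = np.asarray(p, dtype=float) - plane.centroid
        height = float(rel @ plane.unit_normal)
        offset = float(Point(float(rel @ e1), float(rel @ e2)).distance(polygon))
        if abs(height) <= max_height and offset <= max_offset:
            out.append((i, abs(height), offset))
    return out


def validate_pi_pi(candidate: Candidate, criteria: ValidityCriteria):
    """Visual-inspection surrogate for a base-amino-acid candidate.

    Valid iff at least ``min_participating_atoms`` heavy atoms of one
    monomer lie over the other monomer's aromatic face.  Returns
    ``(valid, reason, n_base_over_aa, n_aa_over_base)``.
    """
    aa, base = candidate.aromatic, candidate.partner
    aa_plane, ae1, ae2, aa_poly = _face_frame(aa)
    base_plane, be1, be2, base_poly = _face_frame(base)
    base_over_aa = _participation(base.heavy_points(), aa_plane, ae1, ae2, aa_poly,
                                  criteria.max_perpendicular_height,
                                  criteria.max_lateral_offset)
    aa_over_base = _participation(aa.heavy_points(), base_plane, be1, be2, base_poly,
                                  criteria.max_perpendicular_height,
                                  criteria.max_lateral_offset)
    nb, na = len(base_over_aa), len(aa_over_base)
    need = criteria.min_participating_atoms
    if nb >= need or na >= need:
        return True, "", nb, na
    return False, (f"no face overlap: {nb} base atoms over amino-acid face, "
                   f"{na} amino-acid atoms over base face"), nb, na


def assign_edge_role(omega: float, n_base_over_aa: int, n_aa_over_base: int,
                     min_participating: int = 2) -> str:
    """Edge role of a validated pi-pi contact.

    Stacked contacts (omega < 20) are face-to-face.  Otherwise the
    monomer whose atoms sit over the other's face is the edge; when both
    qualify the tie breaks toward the monomer with more participating
    atoms, then toward the nucleobase.
    """
    if omega < 20.0:
        return "face_face"
    base_ok = n_base_over_aa >= min_participating
    aa_ok = n_aa_over_base >= min_participating
    if base_ok and not aa_ok:
        return "nucleobase_edge"
    if aa_ok and not base_ok:
        return "amino_acid_edge"
    if n_aa_over_base > n_base_over_aa:
        return "amino_acid_edge"
    return "nucleobase_edge"


def classify_pi_pi(candidate: Candidate, criteria: ValidityCriteria,
                   entry_id: str = "") -> PiPiContact:
    aa, base = candidate.aromatic, candidate.partner
    omega = float(np.clip(tilt_angle(aa.plane(), base.plane()), 0.0, 90.0))
    valid, reason, nb, na = validate_pi_pi(candidate, criteria)
    category = edge_role = None
    if valid:
        category = classify_tilt(omega)
        edge_role = assign_edge_role(omega, nb, na,
                                     criteria.min_participating_atoms)
    return PiPiContact(entry_id=entry_id,
                       base_id=base.residue_id, aa_id=aa.residue_id,
                       base_resname=base.residue_name, aa_resname=aa.residue_name,
                       omega=omega, d_min=candidate.d_min,
                       category=category, edge_role=edge_role,
                       valid=valid, reason=reason)


def label_sugar_atoms(sugar: Moiety) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Build idealized hydrogens on a deoxyribose and label them.

    Returns ``label -> (atom position, bonded heavy-atom position)``;
    the entry for O4' maps to ``(O4' position, None)``.  The a/b
    distinction at C2' and C5' follows a fixed local-chirality rule
    (sign of a triple product), so labels are invariant under rigid
    motion and swap consistently for a mirror-image sugar:

    * C2': b is the hydrogen with negative component along
      (C1'-C2') x (C3'-C2') — the one cofacial with H1a in a natural
      D-sugar;
    * C5': a is the hydrogen with positive component along
      (C4'-C5') x (O5'-C5').
    """
    a = sugar.atoms
    for name in ("C1'", "C2'", "C3'", "C4'", "O4'"):
        if name not in a:
            raise GeometryError(f"sugar {sugar.residue_id} missing {name}")
    glyco = next((g for g in ("N9", "N1") if g in a), None)

    labels: dict[str, tuple] = {"O4'": (a["O4'"], None)}

    if glyco is not None:
        h1 = build_hydrogens(a["C1'"], [a["O4'"], a["C2'"], a[glyco]], 1)[0]
        labels["H1a"] = (h1, a["C1'"])

    h2 = build_hydrogens(a["C2'"], [a["C1'"], a["C3'"]], 2)
    v2 = np.cross(a["C1'"] - a["C2'"], a["C3'"] - a["C2'"])
    h2 = sorted(h2, key=lambda h: -float(np.dot(h - a["C2'"], v2)))
    labels["H2a"], labels["H2b"] = (h2[0], a["C2'"]), (h2[1], a["C2'"])

    if "O3'" in a:
        h3 = build_hydrogens(a["C3'"], [a["C2'"], a["C4'"], a["O3'"]], 1)[0]
        labels["H3"] = (h3, a["C3'"])

    if "C5'" in a:
        h4 = build_hydrogens(a["C4'"], [a["C3'"], a["O4'"], a["C5'"]], 1)[0]
        labels["H4"] = (h4, a["C4'"])
        if "O5'" in a:
            h5 = build_hydrogens(a["C5'"], [a["C4'"], a["O5'"]], 2)
            v5 = np.cross(a["C4'"] - a["C5'"], a["O5'"] - a["C5'"])
            h5 = sorted(h5, key=lambda h: -float(np.dot(h - a["C5'"], v5)))
            labels["H5a"], labels["H5b"] = (h5[0], a["C5'"]), (h5[1], a["C5'"])
    return labels


def classify_sugar_contact(candidate: Candidate, criteria: ValidityCriteria,
                           entry_id: str = "") -> SugarPiContact:
    """Classify a sugar-amino-acid candidate by the five-edge taxonomy.

    Each labelled hydrogen and the ring oxygen O4' is tested for
    participation against the aromatic face (height, lateral offset and,
    for hydrogens, the C-H...pi directionality angle); the edge class
    follows from the participating set.
    """
    aa, sugar = candidate.aromatic, candidate.partner
    plane, e1, e2, polygon = _face_frame(aa)
    labels = label_sugar_atoms(sugar)

    # normal direction pointing from the aromatic plane toward the sugar
    sugar_centroid = sugar.ring_points().mean(axis=0)
    n_to_sugar = plane.unit_normal
    if float((sugar_centroid - plane.centroid) @ n_to_sugar) < 0:
        n_to_sugar = -n_to_sugar

    participating: dict[str, tuple[float, float]] = {}
    for label in SUGAR_LABELS:
        if label not in labels:
            continue
        pos, heavy = labels[label]
        rel = pos - plane.centroid
        height = float(rel @ n_to_sugar)
        offset = float(Point(float(rel @ e1), float(rel @ e2)).distance(polygon))
        if not (0.0 < height <= criteria.sugar_max_height
                and offset <= criteria.sugar_max_offset):
            continue
        if heavy is not None:
            direction = pos - heavy  # C-H...pi directionality
        else:
            # lone-pair...pi directionality: the O4' lone pairs point along
            # the external bisector of C1'-O4'-C4'
            a = sugar.atoms
            u1 = _unit(a["C1'"] - pos)
            u2 = _unit(a["C4'"] - pos)
            direction = -(u1 + u2)
        cosang = float(np.dot(_unit(direction), -n_to_sugar))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle > criteria.sugar_ch_angle_max:
            continue
        participating[label] = (height, offset)

    h_labels = [l for l in SUGAR_H_ORDER if l in participating]
    has_o4 = "O4'" in participating
    reason = ""
    if not participating:
        edge_class = None
        valid = False
        reason = "no participating sugar atoms over the aromatic face"
    elif has_o4 and not h_labels:
        edge_class, valid = "lone_pair", True
    elif has_o4:
        edge_class, valid = "lone_pair_proton", True
    else:
        if len(h_labels) > 3:
            # keep the 3 closest hydrogens, note the overflow
            h_sorted = sorted(h_labels, key=lambda l: participating[l][0])[:3]
            reason = (f"{len(h_labels)} participating hydrogens; classified as "
                      f"face using the 3 closest")
            h_labels = [l for l in SUGAR_H_ORDER if l in h_sorted]
        edge_class = {1: "single_proton", 2: "bridged", 3: "face"}[len(h_labels)]
        valid = True

    parts = (["O4'"] if has_o4 else []) + h_labels
    return SugarPiContact(entry_id=entry_id,
                          sugar_id=sugar.residue_id, aa_id=aa.residue_id,
                          sugar_resname=sugar.residue_name,
                          aa_resname=aa.residue_name,
                          edge_class=edge_class,
                          atom_labels=LABEL_SEPARATOR.join(parts),
                          d_min=candidate.d_min, valid=valid, reason=reason,
                          participation={l: participating[l] for l in parts
                                         if l in participating})


def survey_structure(source, criteria: ValidityCriteria | None = None,
                     entry_id: str = ""):
    """Run the full survey on one structure.

    ``source`` is a path, a list of AtomRecords, or a list of Moieties.
    Returns ``(pi_contacts, sugar_contacts, skipped)``; the contact
    lists are deterministic (sorted by residue identifiers) and include
    invalid candidates with their rejection reason.
    """
    criteria = criteria or ValidityCriteria()
    skipped = []
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        atoms = read_structure(source)
        moieties, skipped = extract_moieties(atoms)
    elif source and isinstance(source[0], Moiety):
        moieties = source
    else:
        moieties, skipped = extract_moieties(source)

    pi_contacts, sugar_contacts = [], []
    for cand in screen_candidates(moieties, criteria.cutoff):
        if cand.kind == "pi_pi":
            pi_contacts.append(classify_pi_pi(cand, criteria, entry_id))
        else:
            sugar_contacts.append(classify_sugar_contact(cand, criteria, entry_id))
    return pi_contacts, sugar_contacts, skipped


def contacts_to_dataframe(pi_contacts, sugar_contacts) -> pd.DataFrame:
    """One row per contact, in the survey's tabular output schema."""
    rows = []
    for c in pi_contacts:
        rows.append({
            "entry_id": c.entry_id, "contact_type": "pi_pi",
            "base_or_sugar_residue": c.base_id, "aa_residue": c.aa_id,
            "base_or_sugar_resname": c.base_resname, "aa_resname": c.aa_resname,
            "omega_deg": round(c.omega, 3), "d_min_angstrom": round(c.d_min, 3),
            "category": c.category or "",
            "edge_role_or_atom_labels": c.edge_role or "",
            "valid": c.valid, "reason": c.reason,
        })
    for c in sugar_contacts:
        rows.append({
            "entry_id": c.entry_id, "contact_type": "sugar_pi",
            "base_or_sugar_residue": c.sugar_id, "aa_residue": c.aa_id,
            "base_or_sugar_resname": c.sugar_resname, "aa_resname": c.aa_resname,
            "omega_deg": np.nan, "d_min_angstrom": round(c.d_min, 3),
            "category": c.edge_class or "",
            "edge_role_or_atom_labels": c.atom_labels,
            "valid": c.valid, "reason": c.reason,
        })
    columns = ["entry_id", "contact_type", "base_or_sugar_residue", "aa_residue",
               "base_or_sugar_resname", "aa_resname", "omega_deg",
               "d_min_angstrom", "category", "edge_role_or_atom_labels",
               "valid", "reason"]
    return pd.DataFrame(rows, columns=columns)
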