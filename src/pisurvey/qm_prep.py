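"""Truncated dimer models for external quantum-chemistry engines.

The survey's contacts are converted into capped monomer pairs: the free
nucleobase (backbone replaced by a hydrogen at the glycosidic nitrogen),
the aromatic side chain truncated at the ring (benzene, phenol,
imidazole, indole; His in delta/epsilon/cationic protonation variants,
Tyr with clockwise/counter-clockwise hydroxyl orientations), and the
deoxyribose truncated by replacing the base and both backbone phosphorus
atoms with hydrogens, recording the crystal-derived
C4'-C5'-O5'-H and C4'-C3'-O3'-H dihedrals that those caps freeze.

No electronic-structure code is invoked here: geometries are written as
XYZ (plus a JSON sidecar carrying fragment ranges for counterpoise
bookkeeping), and the module implements only the energy arithmetic —
the dimer binding energy Delta E = E_dimer - E_aa - E_nt, the two-point
inverse-cube correlation-energy extrapolation to the complete-basis-set
limit, and the delta-CCSD(T) composite estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (CH_BOND, GeometryError, NH_BOND, OH_BOND,
                       build_hydrogens, dihedral, place_atom, superpose)
from .structure_io import Moiety

__all__ = [
    "CappedMonomer",
    "EnergyRecord",
    "CompositeEnergySpec",
    "HARTREE_TO_KJ",
    "PRODUCTION_LEVEL",
    "cap_nucleobase",
    "cap_amino_acid",
    "cap_sugar",
    "expand_variants",
    "overlay_reference",
    "binding_energy",
    "cbs_extrapolate",
    "ccsdt_cbs_estimate",
    "write_dimer_geometry",
    "write_dimer_set",
    "read_xyz",
    "read_energies",
]

HARTREE_TO_KJ = 2625.4996
PRODUCTION_LEVEL = "M06-2X/6-31+G(d,p)"  # survey production level tag

_SP2_CH = 1.08


@dataclass
class CappedMonomer:
    """A QM-ready truncated monomer.

    ``atoms`` is a list of ``(element, name, position)``; ``cap_atoms``
    indexes the hydrogens added by truncation.  ``frozen_dihedrals`` maps
    an atom-name quadruple to the crystal-derived value (degrees) that an
    external optimizer must keep fixed.
    """

    kind: str  # nucleobase | aromatic_aa | deoxyribose
    residue_name: str
    atoms: list = field(default_factory=list)
    cap_atoms: list = field(default_factory=list)
    variant_tag: str = "none"
    frozen_dihedrals: list = field(default_factory=list)
    charge: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def formula(self) -> str:
        counts: dict[str, int] = {}
        for element, _, _ in self.atoms:
            counts[element] = counts.get(element, 0) + 1
        order = ["C", "H", "N", "O"]
        keys = [k for k in order if k in counts] + sorted(
            k for k in counts if k not in order)
        return "".join(f"{k}{counts[k] if counts[k] > 1 else ''}" for k in keys)

    def positions(self) -> np.ndarray:
        return np.array([p for _, _, p in self.atoms])


def _sp2_hydrogen(atoms: dict, center: str, n1: str, n2: str,
                  bond: float) -> np.ndarray:
    c = atoms[center]
    u1 = atoms[n1] - c
    u2 = atoms[n2] - c
    d = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
    return c + bond * d / np.linalg.norm(d)


def _along(atoms: dict, center: str, toward: str, bond: float) -> np.ndarray:
    v = atoms[toward] - atoms[center]
    return atoms[center] + bond * v / np.linalg.norm(v)


# free-base hydrogen recipes: (H name, kind, args)
#   ring_ch / ring_nh: sp2 H on external bisector
#   amino: two planar H on an exocyclic N
#   methyl: three H, staggered relative to a ring reference
_BASE_RECIPES = {
    "DA": {"glyco": "N9",
           "hydrogens": [("H8", "ring_ch", ("C8", "N7", "N9")),
                         ("H2", "ring_ch", ("C2", "N1", "N3")),
                         ("H61", "amino", ("N6", "C6", "N1")),
                         ("H62", "amino", ("N6", "C6", "C5"))]},
    "DG": {"glyco": "N9",
           "hydrogens": [("H8", "ring_ch", ("C8", "N7", "N9")),
                         ("H1", "ring_nh", ("N1", "C2", "C6")),
                         ("H21", "amino", ("N2", "C2", "N1")),
                         ("H22", "amino", ("N2", "C2", "N3"))]},
    "DC": {"glyco": "N1",
           "hydrogens": [("H5", "ring_ch", ("C5", "C4", "C6")),
                         ("H6", "ring_ch", ("C6", "C5", "N1")),
                         ("H41", "amino", ("N4", "C4", "N3")),
                         ("H42", "amino", ("N4", "C4", "C5"))]},
    "DT": {"glyco": "N1",
           "hydrogens": [("H6", "ring_ch", ("C6", "C5", "N1")),
                         ("H3", "ring_nh", ("N3", "C2", "C4")),
                         ("H71", "methyl", ("C7", "C5", "C4")),
                         ("H72", "methyl2", ()),
                         ("H73", "methyl3", ())]},
}

_FREE_BASE_NAME = {"DA": "adenine", "DC": "cytosine",
                   "DG": "guanine", "DT": "thymine"}


def cap_nucleobase(moiety: Moiety, c1_position=None) -> CappedMonomer:
    """Free nucleobase: backbone replaced by a hydrogen at the glycosidic
    nitrogen, placed along the former C1' direction (N-H 1.01 A);
    remaining base hydrogens built ideally in the ring plane."""
    if moiety.kind != "nucleobase_ring":
        raise ValueError("cap_nucleobase expects a nucleobase_ring moiety")
    recipe = _BASE_RECIPES[moiety.residue_name]
    atoms = dict(moiety.atoms)
    needed = set(moiety.ring_atom_names) | set(moiety.exocyclic_present)
    missing = [n for n in needed if n not in atoms]
    if missing:
        raise GeometryError(f"missing base atoms: {missing}")

    out = [( _element(n), n, np.asarray(atoms[n], dtype=float))
           for n in list(moiety.ring_atom_names) + list(moiety.exocyclic_present)]
    caps = []
    glyco = recipe["glyco"]
    if c1_position is None and "C1'" in atoms:
        c1_position = atoms["C1'"]
    if c1_position is not None:
        hpos = atoms[glyco] + NH_BOND * _unit(np.asarray(c1_position) - atoms[glyco])
    else:
        neighbours = _ring_neighbours(moiety, glyco)
        hpos = _sp2_hydrogen(atoms, glyco, *neighbours, NH_BOND)
    caps.append(len(out))
    out.append(("H", "H" + glyco[1:], hpos))

    methyl_hs = []
    for name, kind, args in recipe["hydrogens"]:
        if kind == "ring_ch":
            out.append(("H", name, _sp2_hydrogen(atoms, *args, _SP2_CH)))
        elif kind == "ring_nh":
            out.append(("H", name, _sp2_hydrogen(atoms, *args, NH_BOND)))
        elif kind == "amino":
            n_at, c_at, ref = args
            # planar trigonal: H trans to the chosen ring neighbour of c_at
            h = place_atom(atoms[ref], atoms[c_at], atoms[n_at],
                           NH_BOND, 120.0, 180.0)
            out.append(("H", name, h))
        elif kind == "methyl":
            c_at, ring_at, ref = args
            methyl_hs = build_hydrogens(atoms[c_at], [atoms[ring_at]], 3,
                                        reference_dihedral=90.0,
                                        pre_reference=atoms[ref],
                                        bond_length=CH_BOND)
            out.append(("H", name, methyl_hs[0]))
        elif kind == "methyl2":
            out.append(("H", name, methyl_hs[1]))
        elif kind == "methyl3":
            out.append(("H", name, methyl_hs[2]))
    return CappedMonomer(kind="nucleobase", residue_name=moiety.residue_name,
                         atoms=out, cap_atoms=caps)


def _ring_neighbours(moiety: Moiety, name: str):
    ring = list(moiety.ring_atom_names)
    # neighbours in cycle order for 6-rings; for the purine N9 use C8/C4
    if name == "N9":
        return "C8", "C4"
    if name == "N1":
        return "C2", "C6"
    i = ring.index(name)
    return ring[i - 1], ring[(i + 1) % len(ring)]


_AA_RING_H = {
    # aromatic H positions on the truncated side chain (external bisector)
    "PHE": [("CD1", "CG", "CE1"), ("CD2", "CG", "CE2"), ("CE1", "CD1", "CZ"),
            ("CE2", "CD2", "CZ"), ("CZ", "CE1", "CE2")],
    "TYR": [("CD1", "CG", "CE1"), ("CD2", "CG", "CE2"), ("CE1", "CD1", "CZ"),
            ("CE2", "CD2", "CZ")],
    "TRP": [("CD1", "CG", "NE1"), ("CE3", "CD2", "CZ3"), ("CZ2", "CE2", "CH2"),
            ("CZ3", "CE3", "CH2"), ("CH2", "CZ2", "CZ3")],
    "HIS": [("CD2", "CG", "NE2"), ("CE1", "ND1", "NE2")],
}

_FREE_AA_NAME = {"PHE": "benzene", "TYR": "phenol",
                 "HIS": "imidazole", "TRP": "indole"}


def cap_amino_acid(moiety: Moiety, variant: str = "none") -> CappedMonomer:
    """Truncate an aromatic side chain at the ring.

    Phe -> benzene, Tyr -> phenol, His -> imidazole, Trp -> indole; the
    C-beta link is replaced by a hydrogen on CG.  ``variant`` selects the
    His protonation model (``His_delta`` / ``His_epsilon`` / ``His_plus``)
    or the Tyr hydroxyl orientation (``Tyr_CW`` / ``Tyr_CCW``).
    """
    if moiety.kind != "aromatic_aa_ring":
        raise ValueError("cap_amino_acid expects an aromatic_aa_ring moiety")
    resname = moiety.residue_name
    atoms = dict(moiety.atoms)
    out = [(_element(n), n, np.asarray(atoms[n], dtype=float))
           for n in moiety.ring_atom_names]
    if resname == "TYR":
        if "OH" not in atoms:
            raise GeometryError("Tyr missing OH")
        out.append(("O", "OH", np.asarray(atoms["OH"], dtype=float)))

    caps = []
    # cap replacing the C-beta link
    if "CB" in atoms:
        hcg = _along(atoms, "CG", "CB", CH_BOND)
    else:
        pair = {"PHE": ("CD1", "CD2"), "TYR": ("CD1", "CD2"),
                "HIS": ("ND1", "CD2"), "TRP": ("CD1", "CD2")}[resname]
        hcg = _sp2_hydrogen(atoms, "CG", *pair, CH_BOND)
    caps.append(len(out))
    out.append(("H", "HG", hcg))

    for center, n1, n2 in _AA_RING_H[resname]:
        out.append(("H", "H" + center[1:], _sp2_hydrogen(atoms, center, n1, n2,
                                                         _SP2_CH)))
    charge = 0
    if resname == "HIS":
        protons = {"His_delta": ("ND1",), "His_epsilon": ("NE2",),
                   "His_plus": ("ND1", "NE2"), "none": ("NE2",)}
        if variant not in protons:
            raise ValueError(f"unknown His variant {variant!r}")
        for n_at in protons[variant]:
            n1, n2 = {"ND1": ("CG", "CE1"), "NE2": ("CE1", "CD2")}[n_at]
            out.append(("H", "H" + n_at[1:], _sp2_hydrogen(atoms, n_at, n1, n2,
                                                           NH_BOND)))
        charge = 1 if variant == "His_plus" else 0
    elif resname == "TRP":
        out.append(("H", "HE1", _sp2_hydrogen(atoms, "NE1", "CD1", "CE2",
                                              NH_BOND)))
    elif resname == "TYR":
        # hydroxyl H in the ring plane, on either side
        tor = {"Tyr_CW": 0.0, "Tyr_CCW": 180.0, "none": 0.0}.get(variant)
        if tor is None:
            raise ValueError(f"unknown Tyr variant {variant!r}")
        h = place_atom(atoms["CE1"], atoms["CZ"], atoms["OH"], OH_BOND,
                       109.5, tor)
        out.append(("H", "HH", h))
    return CappedMonomer(kind="aromatic_aa", residue_name=resname, atoms=out,
                         cap_atoms=caps, variant_tag=variant, charge=charge)


def expand_variants(moiety: Moiety) -> list[CappedMonomer]:
    """All capped variants of an aromatic side chain: three His
    protonation states, two Tyr hydroxyl orientations, else one model."""
    if moiety.residue_name == "HIS":
        tags = ("His_delta", "His_epsilon", "His_plus")
    elif moiety.residue_name == "TYR":
        tags = ("Tyr_CW", "Tyr_CCW")
    else:
        tags = ("none",)
    return [cap_amino_acid(moiety, v) for v in tags]


def cap_sugar(moiety: Moiety, p5_position=None, p3_position=None,
              default_dihedral: float = 180.0) -> CappedMonomer:
    """Truncated deoxyribose model (18 atoms, C5H10O3).

    The base is replaced by a hydrogen at C1' along the former glycosidic
    direction; the 5' and 3' phosphorus atoms are replaced by hydroxyl
    hydrogens whose C4'-C5'-O5'-H and C4'-C3'-O3'-H dihedrals are frozen
    to the crystal O-P directions (``p5_position`` / ``p3_position``,
    else the residue's own P for the 5' side).  A terminus without a
    phosphorus gets its cap at ``default_dihedral`` and is flagged in
    the frozen-dihedral list.
    """
    if moiety.kind != "deoxyribose":
        raise ValueError("cap_sugar expects a deoxyribose moiety")
    a = moiety.atoms
    heavy = ["C1'", "C2'", "C3'", "C4'", "O4'", "C5'", "O5'", "O3'"]
    missing = [n for n in heavy if n not in a]
    if missing:
        raise GeometryError(f"missing sugar atoms: {missing}")
    out = [(_element(n), n, np.asarray(a[n], dtype=float)) for n in heavy]
    caps = []
    frozen = []

    glyco = next((g for g in ("N9", "N1") if g in a), None)
    if glyco is not None:
        h1cap = a["C1'"] + CH_BOND * _unit(a[glyco] - a["C1'"])
        h1a = build_hydrogens(a["C1'"], [a["O4'"], a["C2'"], a[glyco]], 1)[0]
    else:
        h1pair = build_hydrogens(a["C1'"], [a["O4'"], a["C2'"]], 2)
        h1cap, h1a = h1pair[0], h1pair[1]
    caps.append(len(out))
    out.append(("H", "H1b", h1cap))
    out.append(("H", "H1a", h1a))

    for i, h in enumerate(build_hydrogens(a["C2'"], [a["C1'"], a["C3'"]], 2)):
        out.append(("H", f"H2{'ab'[i]}", h))
    out.append(("H", "H3", build_hydrogens(a["C3'"], [a["C2'"], a["C4'"],
                                                      a["O3'"]], 1)[0]))
    out.append(("H", "H4", build_hydrogens(a["C4'"], [a["C3'"], a["O4'"],
                                                      a["C5'"]], 1)[0]))
    for i, h in enumerate(build_hydrogens(a["C5'"], [a["C4'"], a["O5'"]], 2)):
        out.append(("H", f"H5{'ab'[i]}", h))

    if p5_position is None and "P" in a:
        p5_position = a["P"]
    for tag, o_name, c_name, p_pos in (("HO5'", "O5'", "C5'", p5_position),
                                       ("HO3'", "O3'", "C3'", p3_position)):
        if p_pos is not None:
            tor = dihedral(a["C4'"], a[c_name], a[o_name], p_pos)
            flagged = False
        else:
            tor = default_dihedral
            flagged = True
        h = place_atom(a["C4'"], a[c_name], a[o_name], OH_BOND, 109.5, tor)
        caps.append(len(out))
        out.append(("H", tag, h))
        frozen.append({"atoms": ("C4'", c_name, o_name, tag),
                       "degrees": float(tor), "default_used": flagged})
    return CappedMonomer(kind="deoxyribose", residue_name=moiety.residue_name,
                         atoms=out, cap_atoms=caps, frozen_dihedrals=frozen)


def overlay_reference(template: CappedMonomer, crystal: Moiety,
                      ring_atom_names=None):
    """Rigidly place an optimized monomer template onto the crystal
    orientation by RMS fitting of the ring heavy atoms.

    Returns ``(positioned CappedMonomer, rmsd)``; the template's internal
    geometry is untouched.
    """
    names = tuple(ring_atom_names or crystal.ring_atom_names)
    by_name = {n: p for _, n, p in template.atoms}
    missing = [n for n in names if n not in by_name or n not in crystal.atoms]
    if missing:
        raise GeometryError(f"ring correspondence incomplete: {missing}")
    mobile = np.array([by_name[n] for n in names])
    reference = np.array([crystal.atoms[n] for n in names])
    t = superpose(mobile, reference)
    moved = [(el, n, t.apply(p[None, :])[0]) for el, n, p in template.atoms]
    placed = CappedMonomer(kind=template.kind, residue_name=template.residue_name,
                           atoms=moved, cap_atoms=list(template.cap_atoms),
                           variant_tag=template.variant_tag,
                           frozen_dihedrals=list(template.frozen_dihedrals),
                           charge=template.charge)
    return placed, t.rmsd


@dataclass(frozen=True)
class EnergyRecord:
    """Dimer + monomer electronic energies at one level of theory."""

    E_dimer: float
    E_aa: float
    E_nt: float
    level_tag: str = PRODUCTION_LEVEL
    units: str = "hartree"  # or "kJ/mol"


def binding_energy(record: EnergyRecord) -> float:
    """Interaction energy Delta E = E_dimer - E_aa - E_nt in kJ/mol
    (negative = attractive)."""
    delta = record.E_dimer - record.E_aa - record.E_nt
    if record.units == "hartree":
        return delta * HARTREE_TO_KJ
    if record.units == "kJ/mol":
        return delta
    raise ValueError(f"unknown units {record.units!r}")


@dataclass(frozen=True)
class CompositeEnergySpec:
    """Inputs of the two-point CBS + delta-CC composite.

    ``E_X``/``E_Y`` are correlation energies at cardinal numbers X < Y;
    ``E_ref_Y`` the mean-field reference at the larger basis;
    ``E_cc_small``/``E_mp2_small`` the small-basis energies entering the
    coupled-cluster correction.
    """

    X: int
    Y: int
    E_X: float
    E_Y: float
    E_ref_Y: float = 0.0
    E_cc_small: float = 0.0
    E_mp2_small: float = 0.0


def cbs_extrapolate(spec: CompositeEnergySpec) -> float:
    """Two-point inverse-cube extrapolation of the correlation energy:
    E_CBS = (Y^3 E_Y - X^3 E_X) / (Y^3 - X^3), plus the large-basis
    reference energy."""
    if spec.X >= spec.Y:
        raise ValueError("cardinal numbers must satisfy X < Y")
    x3, y3 = spec.X ** 3, spec.Y ** 3
    corr = (y3 * spec.E_Y - x3 * spec.E_X) / (y3 - x3)
    return spec.E_ref_Y + corr


def ccsdt_cbs_estimate(e_mp2_cbs: float, e_cc_small: float,
                       e_mp2_small: float) -> float:
    """CCSD(T)/CBS estimate: MP2/CBS plus the small-basis
    CCSD(T) - MP2 difference."""
    return e_mp2_cbs + (e_cc_small - e_mp2_small)


def write_dimer_geometry(monomer_a: CappedMonomer, monomer_b: CappedMonomer,
                         path, entry_id: str = "", comment: str = "") -> dict:
    """Write a dimer as standard XYZ plus a JSON sidecar.

    The sidecar records monomer atom ranges (counterpoise fragment
    definitions), variant tags, charges and frozen dihedrals.
    """
    path = Path(path)
    n = monomer_a.n_atoms + monomer_b.n_atoms
    tags = "+".join(t for t in (monomer_a.variant_tag, monomer_b.variant_tag)
                    if t != "none") or "none"
    header = (f"{entry_id} {monomer_a.residue_name}-{monomer_b.residue_name} "
              f"variant={tags} {comment}").strip()
    lines = [str(n), header]
    for mon in (monomer_a, monomer_b):
        for element, _, pos in mon.atoms:
            lines.append(f"{element:2s} {pos[0]:14.6f} {pos[1]:14.6f} "
                         f"{pos[2]:14.6f}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "entry_id": entry_id,
        "monomers": [
            {"residue": m.residue_name, "kind": m.kind,
             "variant_tag": m.variant_tag, "charge": m.charge,
             "atom_range": r,
             "frozen_dihedrals": m.frozen_dihedrals}
            for m, r in ((monomer_a, [0, monomer_a.n_atoms]),
                         (monomer_b, [monomer_a.n_atoms, n]))],
        "charge": monomer_a.charge + monomer_b.charge,
        "level_tag": PRODUCTION_LEVEL,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return sidecar


def write_dimer_set(partner: CappedMonomer, aromatic_moiety: Moiety,
                    out_dir, stem: str, entry_id: str = "") -> list[Path]:
    """Write one XYZ per aromatic variant (His: three; Tyr: two; else one)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for variant in expand_variants(aromatic_moiety):
        suffix = "" if variant.variant_tag == "none" else f"_{variant.variant_tag}"
        p = out_dir / f"{stem}{suffix}.xyz"
        write_dimer_geometry(variant, partner, p, entry_id=entry_id)
        paths.append(p)
    return paths


def read_xyz(path):
    """Read an XYZ file -> (elements, coordinates, comment)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords), comment


def read_energies(path) -> list[EnergyRecord]:
    """Ingest engine energies from CSV with columns
    ``level_tag, E_dimer, E_aa, E_nt`` (hartree; optional ``cp`` flag)."""
    df = pd.read_csv(path)
    records = []
    for _, r in df.iterrows():
        records.append(EnergyRecord(
            E_dimer=float(r["E_dimer"]), E_aa=float(r["E_aa"]),
            E_nt=float(r["E_nt"]),
            level_tag=str(r.get("level_tag", PRODUCTION_LEVEL)),
            units="hartree"))
    return records


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _element(name: str) -> str:
    return name.strip("'0123456789")[0]
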