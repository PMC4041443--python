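"""Synthetic coordinate fixtures with fully known ground truth.

Stand-in for a survey corpus of real co-crystal structures: idealized
nucleobase / aromatic side-chain / deoxyribose monomers are placed at a
controlled interplanar tilt, vertical rise and lateral offset (pi-pi
dimers) or with a chosen set of sugar atoms presented toward an
aromatic face (sugar-pi fixtures).  Every generated structure is
accompanied by a manifest entry recording the requested geometry and
contact class; the generator verifies at build time — running the same
classifiers the survey uses — that the fixture realizes its request,
and raises otherwise.  The manifest is therefore the single source of
truth for downstream tests.

Default corpus composition follows the observed survey frequencies:
60% nucleobase pi-pi contacts (58/29/13% stacked/inclined/T-shaped,
74% of T-shaped presenting the nucleobase edge) and 40% sugar-pi
contacts (33% bridged, 30% face, 20% single proton, 13% lone pair,
4% lone pair-proton), dominated by the H1a-H2b bridged,
H4-H5a-H5b face and H5a single-proton atom sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .contacts import (Candidate, ValidityCriteria, classify_pi_pi,
                       classify_sugar_contact, classify_tilt, label_sugar_atoms,
                       screen_candidates)
from .geometry import min_heavy_distance, random_rotation, rotation_about_axis
from .structure_io import AtomRecord, extract_moieties, write_structure
from .templates import aromatic_template, deoxyribose_template, nucleobase_template

__all__ = [
    "FixtureManifest",
    "build_pi_dimer",
    "build_sugar_fixture",
    "build_decoy",
    "build_survey_corpus",
    "AA_NAMES",
    "BASE_NAMES",
    "DEFAULT_MIXTURE",
]

AA_NAMES = {"PHE": "PHE", "TYR": "TYR", "TRP": "TRP", "HIS": "HIS",
            "F": "PHE", "Y": "TYR", "W": "TRP", "H": "HIS"}
BASE_NAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT",
              "DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT"}

# corpus mixture over contact classes (fractions sum to 1)
DEFAULT_MIXTURE = {
    "stacked": 0.348,
    "inclined": 0.174,
    "t_shaped": 0.078,
    "single_proton": 0.080,
    "bridged": 0.132,
    "face": 0.120,
    "lone_pair": 0.052,
    "lone_pair_proton": 0.016,
}

PI_CLASSES = ("stacked", "inclined", "t_shaped")
SUGAR_CLASSES = ("single_proton", "bridged", "face", "lone_pair",
                 "lone_pair_proton")

# atom-label sets offered per sugar edge class, most common in nature first
SUGAR_LABEL_SETS = {
    "single_proton": (("H5a",), ("H5b",), ("H3",), ("H2a",)),
    "bridged": (("H1a", "H2b"), ("H2a", "H3"), ("H5a", "H5b")),
    "face": (("H4", "H5a", "H5b"), ("H1a", "H2b", "H4")),
    "lone_pair": (("O4'",),),
    "lone_pair_proton": (("O4'", "H4"), ("O4'", "H1a")),
}

_FRAC_T_BASE_EDGE = 0.74  # T-shaped contacts presenting the nucleobase edge

# ring edge rotated toward the partner's face in tilted constructions;
# chosen so no exocyclic substituent hangs below the leading edge
LEADING_EDGE = {
    "DA": ("C8", "N7"), "DG": ("C8", "N7"),
    "DC": ("C5", "C6"), "DT": ("C6", "N1"),
    "PHE": ("CE1", "CZ"), "TYR": ("CD1", "CE1"),
    "HIS": ("CE1", "NE2"), "TRP": ("CZ3", "CH2"),
}


@dataclass
class FixtureManifest:
    """Ground truth for a generated corpus."""

    seed: int
    entries: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FixtureManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(seed=data["seed"], entries=data["entries"])

    @property
    def contacts(self) -> list:
        return [c for e in self.entries for c in e["contacts"]]

    @property
    def decoys(self) -> list:
        return [d for e in self.entries for d in e["decoys"]]


def _records_from_template(template: dict, resname: str, chain: str,
                           resnum: int) -> list[AtomRecord]:
    recs = []
    for name in sorted(template):
        recs.append(AtomRecord(
            atom_name=name, element=name.strip("'0123456789")[0],
            residue_name=resname, chain_id=chain, residue_number=resnum,
            insertion_code="", position=np.asarray(template[name], dtype=float)))
    return recs


def _transform(template: dict, rotation=None, translation=None) -> dict:
    out = {}
    for k, v in template.items():
        p = np.asarray(v, dtype=float)
        if rotation is not None:
            p = rotation @ p
        if translation is not None:
            p = p + translation
        out[k] = p
    return out


def _moieties_from_records(records):
    moieties, _ = extract_moieties(records)
    return moieties


def _solve_rise(fixed_pts: np.ndarray, mobile_pts: np.ndarray,
                target: float) -> float:
    """Vertical shift of the mobile set attaining a given minimum
    heavy-atom distance to the fixed set (monotone branch, bisection)."""
    z_min = float(mobile_pts[:, 2].min())
    lo = -z_min + 0.05
    hi = -z_min + target + 4.0

    def f(h):
        return min_heavy_distance(fixed_pts,
                                  mobile_pts + np.array([0.0, 0.0, h])) - target

    if f(lo) > 0:
        lo = -z_min + 1e-6
    return float(brentq(f, lo, hi, xtol=1e-10))


def build_pi_dimer(base: str, aa: str, omega: float, rise: float,
                   slide: float = 0.0, twist: float = 0.0,
                   edge: str = "base", jitter: float = 0.0,
                   seed: int | None = None,
                   leading_edge: tuple[str, str] | None = None,
                   criteria: ValidityCriteria | None = None,
                   verify: bool = True):
    """One nucleobase-amino-acid dimer at controlled tilt and separation.

    The ``edge`` monomer ("base" or "aa") is tilted by ``omega`` about an
    in-plane axis over the other monomer's face; the vertical position is
    solved so the measured minimum heavy-atom distance equals ``rise``.
    Returns ``(atom_records, manifest_entry)``; the entry records the
    classification the survey itself assigns to the noise-free geometry.
    """
    if not 0.0 <= omega <= 90.0:
        raise ValueError("omega must be in [0, 90]")
    if rise <= 0:
        raise ValueError("rise must be positive")
    base_res = BASE_NAMES[base.upper()]
    aa_res = AA_NAMES[aa.upper()]
    base_t = nucleobase_template(base_res)
    aa_t = aromatic_template(aa_res)

    if edge == "base":
        face_t, tilt_t = aa_t, base_t
        edge_atoms = leading_edge or LEADING_EDGE[base_res]
    elif edge == "aa":
        face_t, tilt_t = base_t, aa_t
        edge_atoms = leading_edge or LEADING_EDGE[aa_res]
    else:
        raise ValueError("edge must be 'base' or 'aa'")

    # point the leading edge toward -y so it leads downward after the tilt
    mid = (tilt_t[edge_atoms[0]] + tilt_t[edge_atoms[1]]) / 2.0
    auto = -90.0 - np.degrees(np.arctan2(mid[1], mid[0]))
    rot = rotation_about_axis([1, 0, 0], omega) \
        @ rotation_about_axis([0, 0, 1], twist + auto)
    tilt_t = _transform(tilt_t, rotation=rot)

    # solve the vertical placement on the screening atom sets
    face_records = _records_from_template(
        face_t, aa_res if edge == "base" else base_res, "A", 1)
    tilt_records = _records_from_template(
        tilt_t, base_res if edge == "base" else aa_res, "B", 1)
    face_m = _moieties_from_records(face_records)
    tilt_m = _moieties_from_records(tilt_records)
    face_pts = next(m for m in face_m if m.kind != "deoxyribose").heavy_points()
    tilt_pts = next(m for m in tilt_m if m.kind != "deoxyribose").heavy_points()
    tilt_pts = tilt_pts + np.array([slide, 0.0, 0.0])
    h = _solve_rise(face_pts, tilt_pts, rise)
    tilt_t = _transform(tilt_t, translation=np.array([slide, 0.0, h]))

    if edge == "base":
        base_final, aa_final = tilt_t, face_t
    else:
        base_final, aa_final = face_t, tilt_t

    records = (_records_from_template(aa_final, aa_res, "A", 1)
               + _records_from_template(base_final, base_res, "B", 1))
    if jitter > 0:
        rng = np.random.default_rng(seed)
        records = [AtomRecord(
            atom_name=r.atom_name, element=r.element, residue_name=r.residue_name,
            chain_id=r.chain_id, residue_number=r.residue_number,
            insertion_code=r.insertion_code,
            position=r.position + rng.normal(scale=jitter, size=3))
            for r in records]

    entry = {
        "type": "pi_pi", "base": base_res, "aa": aa_res,
        "omega": float(omega), "d_min": float(rise), "slide": float(slide),
        "category": classify_tilt(omega), "edge_role": None,
        "base_id": f"B/{base_res}1", "aa_id": f"A/{aa_res}1",
    }
    if verify:
        # run the survey classifier on the noise-free geometry
        criteria = criteria or ValidityCriteria()
        moieties = _moieties_from_records(records)
        cands = [c for c in screen_candidates(moieties, criteria.cutoff)
                 if c.kind == "pi_pi"]
        if len(cands) != 1:
            raise RuntimeError(f"expected 1 pi-pi candidate, found {len(cands)}")
        contact = classify_pi_pi(cands[0], criteria)
        if jitter == 0:
            if not contact.valid:
                raise RuntimeError(
                    f"constructed dimer rejected: {contact.reason}")
            if abs(contact.omega - omega) > 0.1 \
                    or abs(contact.d_min - rise) > 0.01:
                raise RuntimeError("constructed dimer missed requested geometry")
            if contact.category != classify_tilt(omega):
                raise RuntimeError("constructed dimer missed requested category")
        entry.update(category=contact.category, edge_role=contact.edge_role,
                     base_id=contact.base_id, aa_id=contact.aa_id)
    return records, entry


def build_sugar_fixture(edge_class: str, atom_labels, aa: str,
                        height: float = 3.6, seed: int | None = None,
                        jitter: float = 0.0,
                        criteria: ValidityCriteria | None = None):
    """A deoxyribose-amino-acid fixture realizing one sugar edge class.

    The sugar (C2'-endo template) is oriented so that exactly the
    requested atoms pass the participation test over the aromatic face;
    the orientation is found by aligning the mean direction of the
    requested atoms with the face normal and, when needed, searching a
    small deterministic grid of tilts and separations.  Raises if the
    requested (class, labels, amino acid) combination cannot be built.
    """
    if edge_class not in SUGAR_CLASSES:
        raise ValueError(f"unknown sugar edge class {edge_class!r}")
    atom_labels = tuple(atom_labels)
    n_h = sum(1 for l in atom_labels if l != "O4'")
    expected = {"single_proton": (1, False), "bridged": (2, False),
                "face": (3, False), "lone_pair": (0, True)}
    if edge_class == "lone_pair_proton":
        if "O4'" not in atom_labels or n_h < 1:
            raise ValueError("lone_pair_proton needs O4' plus >=1 hydrogen")
    else:
        nh_want, o4_want = expected[edge_class]
        if n_h != nh_want or (("O4'" in atom_labels) != o4_want):
            raise ValueError(f"labels {atom_labels} inconsistent with "
                             f"{edge_class}")

    aa_res = AA_NAMES[aa.upper()]
    aa_t = aromatic_template(aa_res)
    sugar_t = deoxyribose_template(glyco_name="N1")
    criteria = criteria or ValidityCriteria()

    # target direction: mean over requested atoms of (heavy -> atom) units
    sugar_records = _records_from_template(sugar_t, "DT", "B", 1)
    sugar_m = next(m for m in _moieties_from_records(sugar_records)
                   if m.kind == "deoxyribose")
    labels = label_sugar_atoms(sugar_m)
    ring_centroid = sugar_m.ring_points().mean(axis=0)
    dirs, anchors = [], []
    for label in atom_labels:
        pos, heavy = labels[label]
        if heavy is not None:
            v = pos - heavy
        else:  # O4' lone-pair direction: external bisector of C1'-O4'-C4'
            a = sugar_m.atoms
            u1 = (a["C1'"] - pos) / np.linalg.norm(a["C1'"] - pos)
            u2 = (a["C4'"] - pos) / np.linalg.norm(a["C4'"] - pos)
            v = -(u1 + u2)
        dirs.append(v / np.linalg.norm(v))
        anchors.append(pos)
    u = np.mean(dirs, axis=0)
    u /= np.linalg.norm(u)

    # rotation taking u to -z
    target = np.array([0.0, 0.0, -1.0])
    axis = np.cross(u, target)
    if np.linalg.norm(axis) < 1e-9:
        rot0 = np.eye(3) if u[2] < 0 else rotation_about_axis([1, 0, 0], 180.0)
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(u, target), -1, 1)))
        rot0 = rotation_about_axis(axis, ang)

    anchor = np.mean(anchors, axis=0)

    def attempt(extra_rot, rise):
        rot = extra_rot @ rot0
        placed = _transform(sugar_t, rotation=rot)
        a0 = rot @ anchor
        placed = _transform(placed, translation=-np.array([a0[0], a0[1], 0.0]))
        recs = _records_from_template(placed, "DT", "B", 1)
        sm = next(m for m in _moieties_from_records(recs)
                  if m.kind == "deoxyribose")
        h = _solve_rise(np.array([aa_t[k] for k in aa_t]), sm.heavy_points(), rise)
        placed = _transform(placed, translation=np.array([0.0, 0.0, h]))
        recs = (_records_from_template(aa_t, aa_res, "A", 1)
                + _records_from_template(placed, "DT", "B", 1))
        moieties = _moieties_from_records(recs)
        cands = [c for c in screen_candidates(moieties, criteria.cutoff)
                 if c.kind == "sugar_pi"]
        if len(cands) != 1:
            return None, None
        contact = classify_sugar_contact(cands[0], criteria)
        return recs, contact

    wanted = tuple(l for l in ("O4'",) if l in atom_labels) + tuple(
        l for l in ("H1a", "H2a", "H2b", "H3", "H4", "H5a", "H5b")
        if l in atom_labels)
    wanted_str = "-".join(wanted)

    grid = [(0.0, 0.0, height)]
    for rise in (height, height - 0.2, height + 0.2, height - 0.4, height + 0.4):
        for ax in (0.0, 6.0, -6.0, 12.0, -12.0, 18.0, -18.0, 24.0, -24.0):
            for ay in (0.0, 6.0, -6.0, 12.0, -12.0, 18.0, -18.0, 24.0, -24.0):
                grid.append((ax, ay, rise))
    tried = set()
    for ax, ay, rise in grid:
        key = (round(ax, 1), round(ay, 1), round(rise, 2))
        if key in tried:
            continue
        tried.add(key)
        extra = rotation_about_axis([0, 1, 0], ay) @ rotation_about_axis([1, 0, 0], ax)
        recs, contact = attempt(extra, rise)
        if recs is None or contact is None:
            continue
        if contact.valid and contact.edge_class == edge_class \
                and contact.atom_labels == wanted_str:
            if jitter > 0:
                rng = np.random.default_rng(seed)
                recs = [AtomRecord(
                    atom_name=r.atom_name, element=r.element,
                    residue_name=r.residue_name, chain_id=r.chain_id,
                    residue_number=r.residue_number,
                    insertion_code=r.insertion_code,
                    position=r.position + rng.normal(scale=jitter, size=3))
                    for r in recs]
            entry = {
                "type": "sugar_pi", "aa": aa_res, "edge_class": edge_class,
                "atom_labels": wanted_str, "d_min": float(contact.d_min),
                "sugar_id": contact.sugar_id, "aa_id": contact.aa_id,
            }
            return recs, entry
    raise RuntimeError(
        f"cannot realize sugar fixture {edge_class} {atom_labels} with {aa_res}")


def build_decoy(kind: str, seed: int = 0):
    """Non-contact placements the survey must reject or never screen.

    * ``far``: a stacked-like pair beyond the 5.0 A screen;
    * ``coplanar``: two coplanar rings side by side (close, but no face
      overlap — the classic distance-only false positive);
    * ``sugar_far``: a sugar beside an aromatic ring, close in heavy-atom
      distance but with every hydrogen pointing away from the face.
    """
    rng = np.random.default_rng(seed)
    base_res = str(rng.choice(["DA", "DC", "DG", "DT"]))
    aa_res = str(rng.choice(["PHE", "TYR", "TRP", "HIS"]))
    if kind == "far":
        records, _ = build_pi_dimer(base_res, aa_res,
                                    omega=float(rng.uniform(0, 15)),
                                    rise=6.2, verify=False)
    elif kind == "coplanar":
        aa_t = aromatic_template(aa_res)
        base_t = nucleobase_template(base_res)
        aa_pts = np.array(list(aa_t.values()))
        base_pts = np.array(list(base_t.values()))
        gap = 3.4  # closest heavy-atom distance once shifted
        shift = gap + aa_pts[:, 0].max() - base_pts[:, 0].min()
        base_t = _transform(base_t, translation=np.array([shift, 0.0, 0.0]))
        records = (_records_from_template(aa_t, aa_res, "A", 1)
                   + _records_from_template(base_t, base_res, "B", 1))
    elif kind == "sugar_far":
        aa_t = aromatic_template(aa_res)
        sugar_t = deoxyribose_template(glyco_name="N1")
        aa_pts = np.array(list(aa_t.values()))
        s_pts = np.array([v for k, v in sugar_t.items()])
        shift = 4.2 + aa_pts[:, 0].max() - s_pts[:, 0].min()
        sugar_t = _transform(sugar_t, translation=np.array([shift, 0.0, 0.0]))
        records = (_records_from_template(aa_t, aa_res, "A", 1)
                   + _records_from_template(sugar_t, "DT", "B", 1))
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    entry = {"type": "decoy", "kind": kind, "aa": aa_res}
    return records, entry


def _rigid_scatter(records, rng, origin):
    """Random global rotation + translation to ``origin``."""
    rot = random_rotation(rng)
    center = np.mean([r.position for r in records], axis=0)
    return [AtomRecord(
        atom_name=r.atom_name, element=r.element, residue_name=r.residue_name,
        chain_id=r.chain_id, residue_number=r.residue_number,
        insertion_code=r.insertion_code,
        position=rot @ (r.position - center) + origin)
        for r in records]


def _renumber(records, chain_offset: int):
    """Give each dimer its own residue numbers so one file can hold many."""
    return [AtomRecord(
        atom_name=r.atom_name, element=r.element, residue_name=r.residue_name,
        chain_id=r.chain_id, residue_number=r.residue_number + chain_offset,
        insertion_code=r.insertion_code, position=r.position)
        for r in records]


def _largest_remainder(total: int, weights: dict) -> dict:
    """Integer allocation proportional to ``weights`` summing to ``total``."""
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    exact = w * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in order[:short]:
        counts[i] += 1
    return {k: int(c) for k, c in zip(keys, counts)}


def _plan_contacts(n_contacts: int, mixture: dict, rng) -> list[dict]:
    """Deterministic-proportional class plan: empirical class frequencies
    equal the requested mixture exactly (largest-remainder allocation);
    T-shaped contacts split 74/26 between nucleobase and amino-acid edge."""
    plan = []
    for cls, count in _largest_remainder(n_contacts, mixture).items():
        if cls == "t_shaped":
            n_base = _largest_remainder(count, {"base": _FRAC_T_BASE_EDGE,
                                                "aa": 1 - _FRAC_T_BASE_EDGE})
            plan.extend({"cls": cls, "edge": "base"} for _ in range(n_base["base"]))
            plan.extend({"cls": cls, "edge": "aa"} for _ in range(n_base["aa"]))
        else:
            plan.extend({"cls": cls, "edge": "base"} for _ in range(count))
    rng.shuffle(plan)
    return plan


def _sample_contact(rng, item: dict, jitter):
    """Build one planned contact with randomized parameters."""
    cls = item["cls"]
    aa = str(rng.choice(["PHE", "TYR", "TRP", "HIS"]))
    if cls in PI_CLASSES:
        base = str(rng.choice(["DA", "DC", "DG", "DT"]))
        lo, hi = {"stacked": (0.0, 18.0), "inclined": (22.0, 68.0),
                  "t_shaped": (72.0, 90.0)}[cls]
        omega = float(rng.uniform(lo, hi))
        rise = float(rng.uniform(3.2, 3.8))
        slide = float(rng.uniform(0.0, 1.0)) if cls == "stacked" else 0.0
        return build_pi_dimer(base, aa, omega, rise, slide=slide,
                              edge=item["edge"], jitter=jitter,
                              seed=int(rng.integers(2**31)))
    sets = SUGAR_LABEL_SETS[cls]
    weights = np.array([2.0] + [1.0] * (len(sets) - 1))
    labels = sets[int(rng.choice(len(sets), p=weights / weights.sum()))]
    height = float(rng.uniform(3.4, 3.8))
    # fall back across amino acids if a combination cannot be realized
    aa_order = [aa] + [x for x in ("TRP", "TYR", "PHE", "HIS") if x != aa]
    for candidate_aa in aa_order:
        try:
            return build_sugar_fixture(cls, labels, candidate_aa, height=height,
                                       jitter=jitter,
                                       seed=int(rng.integers(2**31)))
        except RuntimeError:
            continue
    raise RuntimeError(f"could not realize sugar class {cls} {labels}")


def build_survey_corpus(n_structures: int, class_mixture: dict | None = None,
                        seed: int = 0, out_dir=None,
                        contacts_per_structure=1,
                        decoy_fraction: float = 0.15,
                        jitter: float = 0.0) -> tuple[dict, FixtureManifest]:
    """Generate a reproducible corpus of multi-contact structures.

    Returns ``(structures, manifest)`` where ``structures`` maps entry ID
    to a list of AtomRecords; when ``out_dir`` is given each structure is
    also written as a PDB file plus a JSON manifest.
    ``contacts_per_structure`` may be an int or a sequence sampled per
    structure.  Decoy placements are added to a ``decoy_fraction`` of
    structures.  Byte-identical across runs for fixed arguments.
    """
    mixture = dict(class_mixture or DEFAULT_MIXTURE)
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("class mixture must sum to 1")
    rng = np.random.default_rng(seed)
    manifest = FixtureManifest(seed=seed)
    structures: dict[str, list] = {}
    decoy_kinds = ("far", "coplanar", "sugar_far")

    if np.isscalar(contacts_per_structure):
        per_structure = [int(contacts_per_structure)] * n_structures
    else:
        choices = list(contacts_per_structure)
        per_structure = [int(rng.choice(choices)) for _ in range(n_structures)]
    plan = _plan_contacts(sum(per_structure), mixture, rng)
    n_decoys = int(round(decoy_fraction * n_structures))
    decoy_hosts = set(int(i) for i in
                      rng.permutation(n_structures)[:n_decoys])

    for i in range(n_structures):
        entry_id = f"SYN{i:04d}"
        records: list[AtomRecord] = []
        contact_entries, decoy_entries = [], []
        slot = 0
        for _ in range(per_structure[i]):
            recs, entry = _sample_contact(rng, plan.pop(), jitter)
            origin = np.array([40.0 * slot, 0.0, 0.0])
            recs = _rigid_scatter(recs, rng, origin)
            recs = _renumber(recs, 10 * slot)
            offset_ids = {k: _shift_residue_id(entry[k], 10 * slot)
                          for k in entry if k.endswith("_id")}
            entry = {**entry, **offset_ids}
            records.extend(recs)
            contact_entries.append(entry)
            slot += 1
        if i in decoy_hosts:
            kind = decoy_kinds[int(rng.integers(len(decoy_kinds)))]
            recs, entry = build_decoy(kind, seed=int(rng.integers(2**31)))
            recs = _rigid_scatter(recs, rng, np.array([40.0 * slot, 0.0, 0.0]))
            recs = _renumber(recs, 10 * slot)
            records.extend(recs)
            decoy_entries.append(entry)
            slot += 1
        structures[entry_id] = records
        manifest.entries.append({"entry_id": entry_id,
                                 "contacts": contact_entries,
                                 "decoys": decoy_entries})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for entry_id, records in structures.items():
            write_structure(records, out_dir / f"{entry_id}.pdb")
        manifest.to_json(out_dir / "manifest.json")
    return structures, manifest


def _shift_residue_id(rid: str, offset: int) -> str:
    chain, rest = rid.split("/", 1)
    name = rest.rstrip("0123456789")
    num = int(rest[len(name):])
    return f"{chain}/{name}{num + offset}"
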