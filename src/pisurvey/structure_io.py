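"""Coordinate I/O and moiety extraction.

Reads protein-DNA co-crystal structures (PDB, optionally mmCIF) through
gemmi, resolves alternate locations and models to a single conformer, and
extracts the three moiety families the survey works on:

* aromatic amino-acid side-chain rings (Phe, Tyr, His, Trp),
* nucleobase rings (DA, DC, DG, DT),
* deoxyribose units (the five-membered C1'-C2'-C3'-C4'-O4' ring with its
  exocyclic C5'/O5'/O3' atoms tracked).

Moieties with missing ring atoms are never silently dropped: they are
reported as skip records with a reason, so a survey over hundreds of
structures remains auditable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import RingPlane, fit_ring_plane

__all__ = [
    "AtomRecord",
    "MoietyDefinition",
    "Moiety",
    "SkipRecord",
    "DatasetManifestRow",
    "StructureFormatError",
    "EmptyStructureError",
    "AROMATIC_DEFINITIONS",
    "NUCLEOBASE_DEFINITIONS",
    "SUGAR_RING_ATOMS",
    "SUGAR_EXOCYCLIC_ATOMS",
    "read_structure",
    "write_structure",
    "extract_moieties",
    "read_manifest",
    "select_dataset",
]


class StructureFormatError(ValueError):
    """The file could not be parsed as a coordinate format."""


class EmptyStructureError(ValueError):
    """The file parsed but contains no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the selected model, after altloc resolution."""

    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    model_index: int = 1


@dataclass(frozen=True)
class MoietyDefinition:
    moiety_kind: str  # aromatic_aa_ring | nucleobase_ring | deoxyribose
    residue_name: str
    ring_atom_names: tuple
    exocyclic_heavy_names: tuple = ()


# Ring-atom dictionaries (PDB v3 naming).  The Trp indole is treated as one
# nine-atom bicyclic ring system for plane fitting and screening.
AROMATIC_DEFINITIONS = {
    "PHE": MoietyDefinition("aromatic_aa_ring", "PHE",
                            ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "TYR": MoietyDefinition("aromatic_aa_ring", "TYR",
                            ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), ("OH",)),
    "HIS": MoietyDefinition("aromatic_aa_ring", "HIS",
                            ("CG", "ND1", "CD2", "CE1", "NE2")),
    "TRP": MoietyDefinition("aromatic_aa_ring", "TRP",
                            ("CG", "CD1", "CD2", "NE1", "CE2",
                             "CE3", "CZ2", "CZ3", "CH2")),
}

NUCLEOBASE_DEFINITIONS = {
    "DA": MoietyDefinition("nucleobase_ring", "DA",
                           ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
                           ("N6",)),
    "DG": MoietyDefinition("nucleobase_ring", "DG",
                           ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
                           ("O6", "N2")),
    "DC": MoietyDefinition("nucleobase_ring", "DC",
                           ("N1", "C2", "N3", "C4", "C5", "C6"),
                           ("O2", "N4")),
    "DT": MoietyDefinition("nucleobase_ring", "DT",
                           ("N1", "C2", "N3", "C4", "C5", "C6"),
                           ("O2", "O4", "C7")),
}

SUGAR_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")
# heavy atoms used for screening distances on the sugar side
SUGAR_HEAVY_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'", "C5'")
SUGAR_EXOCYCLIC_ATOMS = ("C5'", "O5'", "O3'", "P")

_DNA_RESIDUES = set(NUCLEOBASE_DEFINITIONS)


@dataclass
class Moiety:
    """A named group of atoms (one ring system or one sugar unit)."""

    kind: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    atoms: dict = field(default_factory=dict)  # name -> (3,) position
    ring_atom_names: tuple = ()
    exocyclic_present: tuple = ()

    @property
    def residue_id(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{icode}"

    def ring_points(self) -> np.ndarray:
        return np.array([self.atoms[n] for n in self.ring_atom_names])

    def heavy_points(self) -> np.ndarray:
        """Heavy atoms used for screening distances (ring + exocyclic)."""
        if self.kind == "deoxyribose":
            names = [n for n in SUGAR_HEAVY_ATOMS if n in self.atoms]
        else:
            names = list(self.ring_atom_names) + [
                n for n in self.exocyclic_present if n in self.atoms]
        return np.array([self.atoms[n] for n in names])

    def plane(self) -> RingPlane:
        return fit_ring_plane(self.ring_points(), source_atoms=self.ring_atom_names)


@dataclass(frozen=True)
class SkipRecord:
    residue_id: str
    kind: str
    reason: str


@dataclass(frozen=True)
class DatasetManifestRow:
    entry_id: str
    method: str
    resolution: float
    identity_cluster: str = ""
    release_date: _dt.date | None = None
    identity: float | None = None


def read_structure(path, altloc_policy: str = "highest_occupancy",
                   model_policy: str = "first") -> list[AtomRecord]:
    """Read a coordinate file into a flat list of :class:`AtomRecord`.

    Only the model selected by ``model_policy`` (default: the first) is
    returned.  For alternate locations, exactly one conformer per atom
    survives: the highest-occupancy one, ties broken toward altloc "A"
    (lexicographically smallest letter).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if model_policy != "first":
        raise ValueError(f"unknown model_policy {model_policy!r}")
    model = st[0]

    records: dict[tuple, AtomRecord] = {}
    for chain in model:
        for residue in chain:
            for atom in residue:
                seqid = residue.seqid
                rec = AtomRecord(
                    atom_name=atom.name,
                    element=atom.element.name,
                    residue_name=residue.name,
                    chain_id=chain.name,
                    residue_number=seqid.num,
                    insertion_code=(seqid.icode or "").strip(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=float(atom.occ),
                    altloc=(atom.altloc or "").strip(),
                    model_index=1,
                )
                key = (chain.name, seqid.num, (seqid.icode or "").strip(),
                       residue.name, atom.name)
                prev = records.get(key)
                if prev is None:
                    records[key] = rec
                elif altloc_policy == "highest_occupancy":
                    if (rec.occupancy, _altloc_rank(rec.altloc)) > (
                            prev.occupancy, _altloc_rank(prev.altloc)):
                        records[key] = rec
                else:
                    raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    atoms = list(records.values())
    if not atoms:
        raise EmptyStructureError(f"{path} contains no atoms")
    return atoms


def _altloc_rank(altloc: str) -> float:
    # higher rank wins a tie; blank beats everything, then 'A' > 'B' > ...
    if not altloc:
        return float("inf")
    return -ord(altloc[0])


def write_structure(atoms: list[AtomRecord], path) -> None:
    """Write atoms back out as a PDB file (one model, no altlocs)."""
    st = gemmi.Structure()
    st.name = "pisurvey"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec in atoms:
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
        residue = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if (last.seqid.num == rec.residue_number
                    and last.name == rec.residue_name
                    and (last.seqid.icode or "").strip() == rec.insertion_code):
                residue = last
        if residue is None:
            residue = gemmi.Residue()
            residue.name = rec.residue_name
            residue.seqid = gemmi.SeqId(rec.residue_number, rec.insertion_code or " ")
            chain.add_residue(residue)
            residue = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*map(float, rec.position))
        atom.occ = rec.occupancy
        residue.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def extract_moieties(atoms: list[AtomRecord], definitions: dict | None = None,
                     include_sugars: bool = True):
    """Extract aromatic rings, nucleobase rings and deoxyribose units.

    Returns ``(moieties, skipped)``.  A moiety is only returned when all
    its ring atoms are present; incomplete residues yield a
    :class:`SkipRecord` instead.  Waters, ions and unrecognized residues
    (including RNA) are ignored without a record.
    """
    if definitions is None:
        definitions = {**AROMATIC_DEFINITIONS, **NUCLEOBASE_DEFINITIONS}

    by_residue: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rec in atoms:
        key = (rec.chain_id, rec.residue_number, rec.insertion_code, rec.residue_name)
        if key not in by_residue:
            by_residue[key] = {}
            order.append(key)
        by_residue[key][rec.atom_name] = rec.position

    moieties: list[Moiety] = []
    skipped: list[SkipRecord] = []
    for key in order:
        chain_id, resnum, icode, resname = key
        atom_map = by_residue[key]
        rid = f"{chain_id}/{resname}{resnum}{icode}"
        definition = definitions.get(resname)
        if definition is not None:
            missing = [n for n in definition.ring_atom_names if n not in atom_map]
            if missing:
                skipped.append(SkipRecord(rid, definition.moiety_kind,
                                          f"missing ring atoms: {','.join(missing)}"))
            else:
                names = list(definition.ring_atom_names) + [
                    n for n in definition.exocyclic_heavy_names if n in atom_map]
                # keep C1' (glycosidic direction for capping; not screened)
                if definition.moiety_kind == "nucleobase_ring" \
                        and "C1'" in atom_map:
                    names.append("C1'")
                moieties.append(Moiety(
                    kind=definition.moiety_kind,
                    residue_name=resname, chain_id=chain_id,
                    residue_number=resnum, insertion_code=icode,
                    atoms={n: np.asarray(atom_map[n], dtype=float) for n in names},
                    ring_atom_names=definition.ring_atom_names,
                    exocyclic_present=tuple(
                        n for n in definition.exocyclic_heavy_names if n in atom_map),
                ))
        if include_sugars and resname in _DNA_RESIDUES:
            missing = [n for n in SUGAR_RING_ATOMS if n not in atom_map]
            if missing:
                skipped.append(SkipRecord(rid, "deoxyribose",
                                          f"missing ring atoms: {','.join(missing)}"))
            else:
                names = list(SUGAR_RING_ATOMS) + [
                    n for n in SUGAR_EXOCYCLIC_ATOMS if n in atom_map]
                # the glycosidic nitrogen directs H1' reconstruction
                glyco = "N9" if resname in ("DA", "DG") else "N1"
                if glyco in atom_map:
                    names.append(glyco)
                moieties.append(Moiety(
                    kind="deoxyribose",
                    residue_name=resname, chain_id=chain_id,
                    residue_number=resnum, insertion_code=icode,
                    atoms={n: np.asarray(atom_map[n], dtype=float) for n in names},
                    ring_atom_names=SUGAR_RING_ATOMS,
                    exocyclic_present=tuple(
                        n for n in SUGAR_EXOCYCLIC_ATOMS if n in atom_map),
                ))
    return moieties, skipped


def read_manifest(path) -> list[DatasetManifestRow]:
    """Read a dataset manifest CSV.

    Expected columns: ``entry_id, method, resolution, identity_cluster,
    release_date``; an optional numeric ``identity`` column (fraction)
    enables direct identity filtering.
    """
    df = pd.read_csv(path, dtype={"entry_id": str, "identity_cluster": str})
    rows = []
    for _, r in df.iterrows():
        date = None
        if "release_date" in df.columns and pd.notna(r.get("release_date")):
            date = pd.Timestamp(r["release_date"]).date()
        identity = None
        if "identity" in df.columns and pd.notna(r.get("identity")):
            identity = float(r["identity"])
        rows.append(DatasetManifestRow(
            entry_id=str(r["entry_id"]),
            method=str(r.get("method", "")),
            resolution=float(r["resolution"]),
            identity_cluster=str(r.get("identity_cluster", "") or ""),
            release_date=date,
            identity=identity,
        ))
    return rows


def select_dataset(manifest: list[DatasetManifestRow],
                   max_resolution: float = 2.0,
                   max_identity: float = 0.9,
                   method: str = "X-ray",
                   cutoff_date: _dt.date | None = None) -> list[str]:
    """Apply the survey's dataset filter to a metadata manifest.

    Keeps X-ray entries with resolution strictly better (smaller) than
    ``max_resolution`` released before ``cutoff_date``.  Redundancy control:
    rows carrying a numeric ``identity`` are dropped when
    ``identity >= max_identity``; rows sharing an ``identity_cluster`` label
    are reduced to the best-resolution representative.  Returns entry IDs
    in lexicographic order.
    """
    def method_ok(row):
        return row.method.replace("-", "").replace(" ", "").lower() == \
            method.replace("-", "").replace(" ", "").lower()

    kept = []
    for row in manifest:
        if not method_ok(row):
            continue
        if not row.resolution < max_resolution:
            continue
        if cutoff_date is not None and row.release_date is not None \
                and row.release_date >= cutoff_date:
            continue
        if row.identity is not None and row.identity >= max_identity:
            continue
        kept.append(row)

    best_in_cluster: dict[str, DatasetManifestRow] = {}
    unclustered = []
    for row in kept:
        if row.identity_cluster:
            cur = best_in_cluster.get(row.identity_cluster)
            if cur is None or (row.resolution, row.entry_id) < (cur.resolution,
                                                                cur.entry_id):
                best_in_cluster[row.identity_cluster] = row
        else:
            unclustered.append(row)
    ids = [r.entry_id for r in unclustered] + \
        [r.entry_id for r in best_in_cluster.values()]
    return sorted(ids)
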