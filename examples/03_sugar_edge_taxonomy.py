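"""The five-edge taxonomy of deoxyribose-aromatic contacts.

A deoxyribose can meet an aromatic face with a single C-H (single
proton), two C-H (bridged), three C-H (face), its ring-oxygen lone pair
(O4'), or a lone pair plus a proton.  This script builds one fixture
per class and shows the classifier recovering the participating-atom
labels (H1a..H5b numbering around the sugar; a/b distinguish the two
hydrogens at C2' and C5' by a fixed stereochemical rule).
"""

from pisurvey.contacts import survey_structure
from pisurvey.synth import build_sugar_fixture

cases = [
    ("single_proton", ("H5a",), "TYR"),
    ("bridged", ("H1a", "H2b"), "PHE"),
    ("face", ("H4", "H5a", "H5b"), "TRP"),
    ("lone_pair", ("O4'",), "HIS"),
    ("lone_pair_proton", ("O4'", "H4"), "TYR"),
]
for edge_class, labels, aa in cases:
    records, _ = build_sugar_fixture(edge_class, labels, aa)
    _, sugar, _ = survey_structure(records)
    c = next(x for x in sugar if x.valid)
    print(f"{aa}: {c.edge_class:16s} atoms {c.atom_labels:12s} "
          f"d_min {c.d_min:.2f} A")
print("\nAn atom participates when it sits over the aromatic ring polygon")
print("(within a 1.5 A lateral buffer) at <= 4.0 A height, with its C-H")
print("bond (or the O4' lone-pair direction) within 60 deg of the face")
print("normal - the C-H...pi / lone-pair...pi directionality condition.")
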