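# pisurvey

Geometric survey of **DNA–protein π-interactions**: contacts between the
aromatic amino-acid side chains (Phe, Tyr, His, Trp) and either the DNA
nucleobases (π–π contacts) or the deoxyribose sugar (sugar–π contacts,
realized as C–H···π and/or lone-pair···π interactions).

High-resolution protein–DNA co-crystal structures contain many of these
contacts, but a distance screen alone badly over-counts them: two rings can
be close side by side without any face overlap. `pisurvey` implements the
whole analysis chain for structural biologists and computational chemists
who want these contacts detected, classified and turned into quantum-
chemistry-ready models:

* **Screening** — all (aromatic ring, nucleobase) and (aromatic ring,
  deoxyribose) pairs with closest heavy-atom distance < 5.0 Å.
* **Validation** — an explicit geometric surrogate for expert visual
  inspection: a candidate is a π-interaction only if ≥ 2 atoms of one
  monomer sit over the other's aromatic face (≤ 4.5 Å perpendicular
  height, within the convex ring polygon + 1.5 Å). Coplanar side-by-side
  pairs — the classic distance-only false positive — are rejected.
* **π–π classification** — interplanar tilt ω = arccos |n₁·n₂| between the
  best-fit ring-plane normals, binned as stacked (ω ∈ [0°, 20°)), inclined
  ([20°, 70°)) or T-shaped ([70°, 90°]), with an edge role (nucleobase
  edge vs amino-acid edge) for non-stacked contacts.
* **Sugar–π classification** — the five-edge taxonomy: single proton
  (1 H), bridged (2 H), face (3 H), lone pair (O4′ only), lone
  pair–proton (O4′ + H), with participating atoms named by the sugar
  numbering H1a, H2a/H2b, H3, H4, H5a/H5b, O4′. An atom participates when
  it lies ≤ 4.0 Å over the ring polygon (+1.5 Å buffer) with its C–H bond,
  or the O4′ lone-pair direction, within 60° of the face normal.
* **QM model preparation** — truncated dimers for an external engine:
  free nucleobases (backbone → H at N9/N1), side chains cut at the ring
  (benzene, phenol with CW/CCW hydroxyl, imidazole as Hisδ/Hisε/His⁺,
  indole), and an 18-atom deoxyribose model (C₅H₁₀O₃) whose
  ∠(C4′–C5′–O5′–H) and ∠(C4′–C3′–O3′–H) cap dihedrals are frozen to the
  crystal O–P directions. Energy bookkeeping implements
  ΔE = E<sup>dimer</sup> − E<sup>aa</sup> − E<sup>nt</sup>, the two-point
  inverse-cube extrapolation
  E<sub>corr</sub><sup>CBS</sup> = (Y³E_Y − X³E_X)/(Y³ − X³) and the
  ΔCCSD(T) composite E<sup>MP2/CBS</sup> + (E<sup>CC</sup> −
  E<sup>MP2</sup>)<sub>small basis</sub>.
* **Synthetic structures** — a first-class generator of coordinate
  fixtures with fully known ground truth (requested tilt, separation,
  edge class, atom labels, plus decoys), so the entire pipeline is
  testable without downloading a single crystal structure.

## Worked example

```bash
python examples/02_classify_pi_pi_dimer.py
```

```
T:PHE requested omega=  5.0  ->  measured  5.00 deg, d_min 3.50 A, stacked  face_face
A:TYR requested omega= 47.0  ->  measured 47.00 deg, d_min 3.40 A, inclined nucleobase_edge
C:TRP requested omega= 88.0  ->  measured 88.00 deg, d_min 3.30 A, t_shaped nucleobase_edge
A:PHE requested omega= 85.0  ->  measured 85.00 deg, d_min 3.40 A, t_shaped amino_acid_edge
```

Each line builds an idealized nucleobase–amino-acid dimer at a requested
interplanar tilt and closest heavy-atom separation, then runs the survey
classifier on it: the measured ω and d_min reproduce the construction, the
tilt bin follows the half-open convention, and the edge role identifies
which monomer points its edge at the other's face. The sugar taxonomy
equivalent (`examples/03_sugar_edge_taxonomy.py`) prints, e.g.

```
PHE: bridged          atoms H1a-H2b      d_min 3.60 A
TRP: face             atoms H4-H5a-H5b   d_min 3.60 A
HIS: lone_pair        atoms O4'          d_min 3.60 A
```

— the three most common sugar–π motifs, recovered with their
participating-atom label strings.

## Command line

```bash
pisurvey synth --n 50 --seed 7 --out corpus      # ground-truth fixtures
pisurvey scan corpus --out survey                # screen + classify
pisurvey report --contacts survey/contacts.csv \
    --entries survey/entries.json --out survey   # statistics + plots
pisurvey prep-qm --contacts survey/contacts.csv --out qm
pisurvey config init                             # editable criteria YAML
```

`scan` writes one row per candidate (valid and rejected, with reasons) to
`contacts.csv`; `report` aggregates counts, frequency tables and tilt
(5°-bin) / distance (0.1 Å-bin) histograms; `prep-qm` writes one XYZ +
JSON sidecar per capped dimer variant (three files for His, two for Tyr).
Real PDB/mmCIF files are scanned the same way — point `scan` at any
directory of coordinate files; a dataset manifest CSV (resolution, method,
identity, release date) can be filtered with
`pisurvey.structure_io.select_dataset`.

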