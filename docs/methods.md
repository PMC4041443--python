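# Methods

This note documents the models, geometric criteria and numerical choices
behind `pisurvey`, and what the synthetic-fixture tests do and do not
demonstrate about real crystal structures.

## Moieties and coordinate handling

Structures are read with gemmi (PDB, optionally mmCIF). Only the first
model is used; for alternate locations the conformer with the highest
occupancy survives, ties broken toward altloc "A" — a deterministic
single-conformer view appropriate for a survey of ~2 Å X-ray structures.
Waters, ions and RNA residues are ignored.

Three moiety families are extracted by fixed atom-name dictionaries
(PDB v3 names): aromatic side-chain rings (Phe/Tyr:
CG,CD1,CD2,CE1,CE2,CZ; His: CG,ND1,CD2,CE1,NE2; Trp: the full 9-atom
indole, treated as one ring system for plane fitting), nucleobase rings
(purines: the 9-atom bicyclic; pyrimidines: the 6-ring) and deoxyribose
units (C1′–C4′ + O4′, with C5′/O5′/O3′/P tracked when present). A moiety
is only produced when every ring atom is present; incomplete residues
are reported in a skip log rather than silently dropped.

Dataset selection filters a metadata manifest: X-ray entries with
resolution strictly better than 2.0 Å, released before a cutoff date,
with redundancy control by a numeric identity column (< 0.9) and/or by
keeping the best-resolution representative of each sequence-identity
cluster. No symmetry-mate expansion is performed: the survey analyses
deposited coordinates only, an assumption worth keeping in mind for
contacts across crystallographic interfaces.

## Screening and the visual-inspection surrogate

Candidate pairs are all (aromatic ring, nucleobase) and (aromatic ring,
deoxyribose) pairs whose minimum heavy-atom distance is strictly below
the 5.0 Å cutoff. Screening distances use the moiety heavy atoms: ring
atoms plus exocyclic substituents for bases (O2, N4, O4, C7, N6, O6,
N2), the Tyr hydroxyl oxygen, and C1′–C5′ + O4′ for sugars. The
backbone links (Cβ, C1′ on the base side) are excluded — they belong to
the backbone, not the π-system's moiety.

Whether a close pair is a genuine π-interaction is decided by an
explicit geometric test standing in for expert visual inspection. All
thresholds live in a `ValidityCriteria` config (YAML-editable):

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 5.0 Å | screening distance |
| `max_perpendicular_height` | 4.5 Å | atom height over the partner ring plane (π–π) |
| `max_lateral_offset` | 1.5 Å | buffer around the convex ring polygon |
| `min_participating_atoms` | 2 | atoms of one monomer required over the other's face |
| `sugar_max_height` | 4.0 Å | height limit for sugar H / O4′ participation |
| `sugar_max_offset` | 1.5 Å | lateral buffer for sugar participation |
| `sugar_ch_angle_max` | 60° | max angle of the C–H bond (or O4′ lone-pair direction) to the face normal |

A π–π candidate is valid when at least `min_participating_atoms` heavy
atoms of one monomer lie over the other monomer's aromatic face (within
the height limit, projecting inside the convex hull of the ring atoms
expanded by the lateral buffer). Two coplanar rings that are merely
close side by side have no such atoms and are rejected — this is the
false-positive class that distance-only searches over-count. The
defaults were chosen to accept the canonical stacked (rise ≈ 3.5 Å) and
T-shaped (edge over face) archetypes and reject the coplanar and
beyond-cutoff archetypes on constructed geometries; they are a
documented approximation, and an exact reproduction of any particular
expert's accept/reject decisions is not claimed.

## π–π classification

The tilt ω is the angle between the best-fit ring-plane normals
(least-squares plane via SVD of the centered ring coordinates; exocyclic
atoms excluded from the fit), folded into [0°, 90°] so the arbitrary
normal sign cancels. Bins are half-open so every ω has exactly one
class: stacked [0°, 20°), inclined [20°, 70°), T-shaped [70°, 90°] —
the boundary values 20° and 70° are assigned upward.

For non-stacked contacts the edge role is the monomer whose atoms pass
the participation test against the other's plane ("its edge points at
the other's face"); if both qualify, the tie breaks toward the monomer
with more participating atoms, then toward the nucleobase. Stacked
contacts are face-to-face by definition.

## Sugar–π classification

Crystal structures at survey resolution lack hydrogens, so sugar
hydrogens are always rebuilt geometrically: ideal tetrahedral directions
completing the known heavy-atom substituents, C–H 1.09 Å (O–H 0.96 Å,
N–H 1.01 Å where relevant). This idealized placement is a deterministic
approximation to quantum-mechanical proton optimization; for
classification purposes only the C–H directions matter, and these are
fixed by the heavy-atom frame to within a few degrees.

Labels follow the sugar numbering: H1a (C1′), H2a/H2b (C2′), H3 (C3′),
H4 (C4′), H5a/H5b (C5′), plus the ring oxygen O4′. The a/b distinction
is a fixed local-chirality rule (sign of a triple product of bond
vectors at C2′ and C5′), so labels are invariant under rigid motion and
swap consistently for a mirror-image sugar; in a natural D-sugar, H2b is
the C2′ hydrogen cofacial with H1a — which makes the naturally dominant
H1a–H2b bridged motif a cofacial pair, as it must be.

An atom participates when it sits over the aromatic ring polygon
(buffered) at 0 < height ≤ 4.0 Å **and** points at the face: the C–H
bond within 60° of the face normal for hydrogens, and the O4′ lone-pair
direction — taken as the external bisector of C1′–O4′–C4′ — within 60°
for the ring oxygen. The directionality condition for O4′ mirrors the
C–H···π condition and prevents the ring oxygen from being scored when a
hydrogen face is presented with O4′ merely nearby. O5′/O3′ lone pairs
are not scored (they belong to the phosphate backbone context); a flag
exists for exploration.

The edge class follows from the participating set: O4′ alone →
lone pair; O4′ + ≥ 1 H → lone pair–proton; 1/2/3 H → single proton /
bridged / face. More than three participating hydrogens (possible only
for marginal geometries) classify as face using the three closest, with
a note in the contact's reason field. Candidates with no participating
atom are rejected with a reason. A residue pair exhibiting both a
base–π and a sugar–π geometry yields two contacts; the overlap is
visible in the output table.

## QM model preparation

Truncation replaces backbone context with hydrogens: nucleobases get an
N–H (1.01 Å) along the former glycosidic C1′ direction plus ideally
built base hydrogens (sp2 ring H on external bisectors, planar amino
groups, staggered thymine methyl); side chains are cut at the ring with
an H along the former Cβ direction, giving benzene (12 atoms), phenol
(13), imidazole (9; 10 for the cation) and indole (16). His is emitted
in three protonation variants (δ, ε, cation; net charge +1 for the
cation) and Tyr in two in-plane hydroxyl orientations (CW/CCW, realized
as the ∠(CE1–CZ–OH–H) = 0°/180° rotamers). The deoxyribose model is the
18-atom C₅H₁₀O₃ sugar: base → H at C1′, 5′- and 3′-phosphorus → hydroxyl
hydrogens placed at the crystal ∠(C4′–C5′–O5′–P) and ∠(C4′–C3′–O3′–P)
dihedrals, which are recorded as frozen constraints for the external
optimizer. Terminal residues without a phosphorus get the cap at a
configurable default dihedral (180°) and are flagged.

Dimers are written as standard XYZ with a JSON sidecar carrying monomer
atom ranges (counterpoise fragment definitions), variant tags, charges
and frozen dihedrals. `overlay_reference` rigidly places an optimized
monomer template onto the crystal orientation by Kabsch superposition of
the ring heavy atoms (reflections excluded), leaving internal geometry
untouched. No electronic-structure code is executed; the production
level tag (M06-2X/6-31+G(d,p)) is bookkeeping only.

Energy arithmetic: ΔE = E_dimer − E_aa − E_nt (1 hartree =
2625.4996 kJ/mol; negative = attractive); the two-point correlation-energy
extrapolation E_CBS = (Y³E_Y − X³E_X)/(Y³ − X³) with the mean-field
reference taken at the larger basis (common practice); and the composite
estimate E_MP2/CBS + (E_CC − E_MP2) at the small basis. The inverse-cube
model makes the extrapolation exact on any synthetic E(n) = E_∞ + A·n⁻³
series, which the tests exploit as a closed-form oracle.

## Synthetic structures: what they do and do not show

The generator builds idealized monomers — regular(-fused) polygon rings
with 1.39 Å bonds, a C2′-endo deoxyribose (pseudorotation phase 162°,
amplitude 35°, γ = +54°, natural D chirality verified against an
independently embedded thymidine) — and places them with controlled
geometry: requested interplanar tilt, closest heavy-atom separation
(solved by bisection on the screening atom sets, so the survey's own
distance definition is matched to < 0.01 Å), lateral offset, and leading
ring edge for tilted placements. Sugar fixtures orient a requested atom
set toward the aromatic face and then verify, with the survey's own
classifier, that exactly the requested atoms participate; a small
deterministic grid of tilts and separations is searched when the first
orientation misses. The generator raises rather than emit a fixture
whose ground truth it cannot certify.

Corpus composition is deterministic-proportional (largest-remainder
allocation), so a requested class mixture is realized exactly; the
default mixture follows the observed survey frequencies (60% π–π split
58/29/13 stacked/inclined/T-shaped with 74% of T-shaped presenting the
nucleobase edge; 40% sugar–π split 33/30/20/13/4
bridged/face/single/lone-pair/lone-pair–proton, dominated by the
H1a–H2b, H4–H5a–H5b and H5a atom sets). Decoys (beyond-cutoff pairs,
coplanar side-by-side pairs, sugars presented edge-on past the
directionality test) are added to a configurable fraction of structures.
Corpora are byte-identical across runs for a fixed seed; optional
Gaussian coordinate jitter (σ, default 0) is available.

Passing the full-circle test therefore shows that the pipeline is
*internally consistent and exactly invertible on noise-free, idealized
geometry*: every generated contact is recovered with its class, labels,
tilt (±0.1°, limited only by PDB coordinate precision) and distance
(±0.01 Å), and no decoy is accepted. It does not show that the
validity thresholds reproduce any particular expert's judgement on real,
thermally disordered crystal geometry, where contacts populate the
boundaries of every criterion; on real structures the classifier should
be read as a reproducible operational definition.

## Numerical choices

* Angles in degrees, distances in Å throughout; dihedrals follow the
  IUPAC sign convention (checked against Bio.PDB).
* Plane fits reject collinear input; tilt uses |cos| so it is
  normal-sign-free; superposition excludes reflections via the
  determinant correction in the Kabsch SVD.
* Tilt-bin boundaries are half-open upward (20° → inclined,
  70° → T-shaped); histogram bins are half-open with the last bin
  closed, and out-of-domain values are an error listing the offenders.
* The survey's per-candidate output includes rejected candidates with
  reasons, so reported totals are auditable.
* Problem sizes: the acceptance workflow regenerates and re-surveys a
  200-structure corpus (~4 s) — large enough to populate every class
  and edge role under the default mixture while keeping the whole suite
  interactive.

## Known limitations

* Deposited coordinates only; no symmetry mates, no biological-assembly
  expansion.
* Modified or damaged nucleobases are not in the default dictionaries;
  contacts involving them are skipped (logged), matching the survey's
  selection criteria.
* Hydrogen positions are idealized, not QM-optimized; sugar C–H
  directionality is therefore accurate only to the heavy-atom frame.
* His protonation is not inferred from the environment: the survey
  counts His once, and the three protonation models exist only at the
  QM-preparation stage.
* The validity criteria are a surrogate, not a re-derivation, of human
  inspection; their defaults are documented above and are configurable.
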