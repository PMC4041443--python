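"""Truncated dimer models and interaction-energy bookkeeping.

Caps a stacked adenine:Phe contact into the free-base + benzene dimer
(backbone replaced by hydrogens), writes the XYZ input for an external
quantum-chemistry engine, and demonstrates the energy arithmetic the
package implements: the dimer binding energy Delta E = E_dimer - E_aa -
E_nt, the two-point inverse-cube extrapolation of correlation energies
to the complete-basis-set (CBS) limit, and the delta-CCSD(T) composite.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from pisurvey.qm_prep import (CompositeEnergySpec, EnergyRecord,
                              binding_energy, cap_amino_acid, cap_nucleobase,
                              cbs_extrapolate, ccsdt_cbs_estimate, read_xyz,
                              write_dimer_geometry)
from pisurvey.structure_io import extract_moieties
from pisurvey.synth import build_pi_dimer

records, _ = build_pi_dimer("A", "PHE", omega=5.0, rise=3.5)
moieties, _ = extract_moieties(records)
base = next(m for m in moieties if m.kind == "nucleobase_ring")
aa = next(m for m in moieties if m.kind == "aromatic_aa_ring")

adenine = cap_nucleobase(base)     # free base, H at the glycosidic N9
benzene = cap_amino_acid(aa)       # side chain truncated at the ring
print(f"capped monomers: {adenine.formula()} ({adenine.n_atoms} atoms) + "
      f"{benzene.formula()} ({benzene.n_atoms} atoms)")

with TemporaryDirectory() as td:
    path = Path(td) / "A_Phe.xyz"
    sidecar = write_dimer_geometry(benzene, adenine, path, entry_id="demo")
    elements, _, _ = read_xyz(path)
    print(f"dimer XYZ: {len(elements)} atoms; counterpoise fragments "
          f"{sidecar['monomers'][0]['atom_range']} / "
          f"{sidecar['monomers'][1]['atom_range']}")

# energy arithmetic on illustrative numbers (kJ/mol)
delta = binding_energy(EnergyRecord(E_dimer=-100.0, E_aa=-40.0, E_nt=-50.0,
                                    units="kJ/mol"))
print(f"Delta E = -100 - (-40) - (-50) = {delta:.1f} kJ/mol (attractive)")

# a synthetic n^-3 correlation-energy series is extrapolated exactly
spec = CompositeEnergySpec(X=2, Y=3, E_X=-1.0 + 0.5 / 8, E_Y=-1.0 + 0.5 / 27)
print(f"CBS limit of E(n) = -1.0 + 0.5 n^-3: {cbs_extrapolate(spec):.12f}")
print(f"CCSD(T)/CBS composite of (-20, -18, -15): "
      f"{ccsdt_cbs_estimate(-20.0, -18.0, -15.0):.1f} kJ/mol")
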