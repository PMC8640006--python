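"""Frequencies, enthalpy and heat of formation on the toy baseline.

Optimizes water, computes harmonic frequencies from a finite-difference
Hessian, assembles the HO/RR enthalpy at 298.15 K, and evaluates a heat of
formation from the atomization route with a synthetic atomic-energy table
(planted values, since the toy baseline is not a real electronic-structure
method).
"""

import numpy as np

from deltapot import (enthalpy, harmonic_frequencies, heat_of_formation,
                      hessian, load_templates, optimize_geometry)
from deltapot.synthetic import ToyBaseline
from deltapot.thermo import AtomicEnergyTable, load_atomic_dhf

baseline = ToyBaseline()
opt = optimize_geometry(load_templates()["H2O"], baseline, fmax=1e-6)
mol = opt.molecule
print(f"optimized in {opt.n_iterations} steps, max|F| = {opt.fmax:.1e} Ha/A")

h = hessian(mol, baseline, step=0.005)
freqs, _ = harmonic_frequencies(h, mol.masses, mol.coordinates)
print("harmonic frequencies (cm^-1):", np.round(freqs, 1))

thermo = enthalpy(mol, baseline.energy(mol), freqs, temperature=298.15)
print(f"ZPE = {thermo.zpe:.6f} Ha, H(298.15 K) = {thermo.enthalpy:.6f} Ha")

# synthetic atomic energies consistent with the toy world
table = AtomicEnergyTable({"H": -0.075, "O": -0.15}, load_atomic_dhf())
dhf = heat_of_formation(mol, thermo.enthalpy, table)
print(f"dHf(298 K) = {dhf:.2f} kcal/mol (atomization route, toy energies)")
print("3N-6 = 3 modes for bent H2O; the enthalpy adds ZPE, thermal and pV terms.")
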