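"""Thermochemistry closed forms and heat-of-formation algebra."""

import numpy as np
import pytest

from deltapot.chem import HARTREE_TO_KCALMOL, Molecule
from deltapot.composite import hessian
from deltapot.optimize import optimize_geometry
from deltapot.thermo import (KB_HARTREE, CM_TO_KELVIN, AtomicEnergyTable,
                             enthalpy, fit_atomic_energies,
                             harmonic_frequencies, heat_of_formation,
                             is_linear, load_atomic_dhf)

AMU = {"H": 1.00782503207, "O": 15.9949146196}


def harmonic_diatomic_hessian(k, axis=0):
    """Analytic Cartesian Hessian of E = 1/2 k (x1-x0-r_e)^2 along an axis."""
    h = np.zeros((6, 6))
    i, j = axis, 3 + axis
    h[i, i] = h[j, j] = k
    h[i, j] = h[j, i] = -k
    return h


def test_diatomic_frequency_closed_form():
    # omega = (1/2 pi c) sqrt(k/mu), evaluated independently via constants
    k = 0.35  # Hartree / A^2
    masses = np.array([AMU["H"], AMU["O"]])
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    freqs, modes = harmonic_frequencies(harmonic_diatomic_hessian(k), masses, coords)
    assert len(freqs) == 1
    mu = masses[0] * masses[1] / masses.sum()
    from deltapot.thermo import _FREQ_TO_CM
    expected = np.sqrt(k / mu) * _FREQ_TO_CM
    assert freqs[0] == pytest.approx(expected, rel=1e-3)


def test_atom_has_no_frequencies():
    freqs, modes = harmonic_frequencies(np.zeros((3, 3)), np.array([12.0]),
                                        np.zeros((1, 3)))
    assert len(freqs) == 0


def test_mode_counts_and_rotation_invariance(baseline, templates):
    from scipy.spatial.transform import Rotation
    for name, expected in (("H2O", 3), ("NH3", 6), ("CO2", 4), ("C2H2", 7)):
        mol = optimize_geometry(templates[name], baseline, fmax=1e-6,
                                max_steps=1000).molecule
        h = hessian(mol, baseline)
        freqs, _ = harmonic_frequencies(h, mol.masses, mol.coordinates)
        assert len(freqs) == expected, name
        # rotate the Hessian exactly (block-wise R H R^T): frequencies must
        # be invariant to well below 0.01 cm^-1
        rot = Rotation.random(random_state=1).as_matrix()
        big_r = np.kron(np.eye(mol.n_atoms), rot)
        h_rot = big_r @ h @ big_r.T
        rotated = mol.with_coordinates(mol.coordinates @ rot.T)
        freqs2, _ = harmonic_frequencies(h_rot, rotated.masses,
                                         rotated.coordinates)
        np.testing.assert_allclose(freqs2, freqs, atol=0.01)
        # recomputing the finite-difference Hessian in the rotated frame
        # agrees to the FD truncation level
        h2 = hessian(rotated, baseline)
        freqs3, _ = harmonic_frequencies(h2, rotated.masses, rotated.coordinates)
        np.testing.assert_allclose(freqs3, freqs, atol=2.0)


def test_nonstationary_geometry_warns(baseline, templates):
    stretched = templates["H2"].with_coordinates(
        np.array([[0.0, 0, 0], [0.9, 0, 0]]))
    h = hessian(stretched, baseline)
    with pytest.warns(UserWarning, match="non-stationary"):
        harmonic_frequencies(h, stretched.masses, stretched.coordinates,
                             forces=baseline.forces(stretched))


def test_asymmetric_hessian_rejected():
    h = np.zeros((6, 6)); h[0, 1] = 1.0
    with pytest.raises(ValueError, match="asymmetry"):
        harmonic_frequencies(h, np.array([1.0, 1.0]), np.zeros((2, 3)))


def test_linear_detection():
    assert is_linear(np.array([[0, 0, 0], [1.4, 0, 0], [-1.4, 0, 0]]),
                     np.array([12.0, 16.0, 16.0]))
    assert not is_linear(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                         np.ones(3))


def test_atom_enthalpy_is_five_halves_rt():
    atom = Molecule(("C",), np.zeros((1, 3)))
    t = 298.15
    res = enthalpy(atom, e_elec=-37.8, frequencies=np.array([]), temperature=t)
    assert res.enthalpy - (-37.8) == pytest.approx(2.5 * KB_HARTREE * t, abs=1e-10)


def test_high_frequency_limit_leaves_only_zpe():
    mol = Molecule(("H", "H"), [[0, 0, 0], [0.7, 0, 0]])
    res = enthalpy(mol, 0.0, np.array([1.0e6]), temperature=10.0)
    assert res.thermal_vib == 0.0
    assert res.zpe > 0


def test_diatomic_enthalpy_hand_evaluated():
    # independent scalar evaluation of the HO/RR formula at 2000 cm^-1
    t = 298.15
    omega = 2000.0
    theta = omega * CM_TO_KELVIN
    kt = KB_HARTREE * t
    expected = (0.0 + 0.5 * KB_HARTREE * theta
                + 1.5 * kt + kt                      # trans + linear rot
                + KB_HARTREE * theta / np.expm1(theta / t)
                + kt)                                # pV
    mol = Molecule(("H", "H"), [[0, 0, 0], [0.7, 0, 0]])
    res = enthalpy(mol, 0.0, np.array([omega]), temperature=t)
    assert res.enthalpy == pytest.approx(expected, abs=1e-12)


def test_imaginary_frequencies_rejected_unless_dropped():
    mol = Molecule(("H", "H"), [[0, 0, 0], [0.7, 0, 0]])
    with pytest.raises(ValueError, match="imaginary"):
        enthalpy(mol, 0.0, np.array([-100.0, 2000.0]))
    res = enthalpy(mol, 0.0, np.array([-100.0, 2000.0]), drop_imaginary=True)
    assert res.enthalpy == enthalpy(mol, 0.0, np.array([2000.0])).enthalpy


def test_enthalpy_monotone_in_temperature():
    mol = Molecule(("O", "H", "H"), [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
    freqs = np.array([1600.0, 3650.0, 3750.0])
    hs = [enthalpy(mol, 0.0, freqs, temperature=t).enthalpy
          for t in np.linspace(100, 1000, 10)]
    assert np.all(np.diff(hs) > 0)


# ---- heats of formation -------------------------------------------------


def _planted_world(rng):
    """Molecule set with dHf generated from known atomic energies."""
    e_a = {"H": -0.5, "C": -37.8, "N": -54.5, "O": -75.0}
    dhf_atoms = load_atomic_dhf()
    table = AtomicEnergyTable(e_a, dhf_atoms)
    mols = [
        Molecule(("H", "H"), [[0, 0, 0], [0.7, 0, 0]]),
        Molecule(("C", "H", "H", "H", "H"),
                 np.vstack([np.zeros(3), np.eye(3), [[-1, -1, -1]]]) * 0.63),
        Molecule(("N", "H", "H", "H"), np.vstack([np.zeros(3), np.eye(3)])),
        Molecule(("O", "H", "H"), [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]),
        Molecule(("C", "O", "O"), [[0, 0, 0], [1.2, 0, 0], [-1.2, 0, 0]]),
        Molecule(("C", "N", "H"), [[0, 0, 0], [1.16, 0, 0], [-1.06, 0, 0]]),
    ]
    records = []
    for mol in mols:
        h_calc = (sum(e_a[e] for e in mol.elements)
                  - rng.uniform(0.05, 0.5))  # arbitrary atomization enthalpy
        dhf = heat_of_formation(mol, h_calc, table)
        records.append((mol, h_calc, dhf))
    return e_a, records


def test_fit_atomic_energies_recovers_planted_values(rng):
    e_a, records = _planted_world(rng)
    table, residuals = fit_atomic_energies(records, ["H", "C", "N", "O"])
    for e, v in e_a.items():
        assert table.atomic_energies[e] == pytest.approx(v, abs=1e-8)
    np.testing.assert_allclose(residuals, 0, atol=1e-8)


def test_exactly_determined_system_zero_residuals(rng):
    e_a, records = _planted_world(rng)
    # perturb dHf targets; 4 independent molecules -> exact interpolation
    sub = [(m, h, d + 1.0) for m, h, d in records[:4]]
    table, residuals = fit_atomic_energies(sub, ["H", "C", "N", "O"])
    np.testing.assert_allclose(residuals, 0, atol=1e-8)


def test_fit_rank_deficiency_names_missing_element(rng):
    from deltapot.chem import MoleculeError
    _, records = _planted_world(rng)
    hydrocarbons = [r for r in records if set(r[0].elements) <= {"C", "H"}]
    with pytest.raises(MoleculeError, match="N"):
        fit_atomic_energies(hydrocarbons, ["H", "C", "N"])


def test_single_atom_self_consistency():
    dhf_atoms = load_atomic_dhf()
    table = AtomicEnergyTable({"O": -75.0}, dhf_atoms)
    atom = Molecule(("O",), np.zeros((1, 3)))
    assert heat_of_formation(atom, -75.0, table) == pytest.approx(
        dhf_atoms["O"], abs=1e-10)


def test_hof_extensivity(rng):
    e_a, records = _planted_world(rng)
    table = AtomicEnergyTable(e_a, load_atomic_dhf())
    mol, h_calc, dhf = records[3]
    double = Molecule(mol.elements * 2,
                      np.vstack([mol.coordinates, mol.coordinates + [100, 0, 0]]))
    # doubling a non-interacting system doubles H and the atomization terms
    assert heat_of_formation(double, 2 * h_calc, table) == pytest.approx(
        2 * dhf, abs=1e-8)


def test_hof_hand_oracle():
    # H2 with planted numbers, checked by plain scalar arithmetic
    table = AtomicEnergyTable({"H": -0.5}, {"H": 52.102})
    h2 = Molecule(("H", "H"), [[0, 0, 0], [0.7, 0, 0]])
    h_calc = -1.16
    expected = 2 * 52.102 - (2 * (-0.5) - h_calc) * HARTREE_TO_KCALMOL
    assert heat_of_formation(h2, h_calc, table) == pytest.approx(expected, abs=1e-10)
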