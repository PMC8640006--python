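"""Harmonic frequencies, HO/RR enthalpies and heats of formation.

Frequencies come from the mass-weighted Cartesian Hessian with rigid
translations and rotations projected out in the Eckart frame.  Enthalpies
use ideal-gas harmonic-oscillator / rigid-rotor statistical mechanics
(enthalpy needs no symmetry number).  Heats of formation are computed from
atomization energies with per-element fitted atomic energies plus
experimental atomic heats of formation at 298 K, which ship as an editable
CSV table.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .chem import HARTREE_TO_KCALMOL, Molecule, MoleculeError, composition_vector

# physical constants
KB_HARTREE = 3.166811563e-6       # Boltzmann constant, Hartree/K
HARTREE_J = 4.3597447222071e-18
AMU_KG = 1.66053906660e-27
C_CM_S = 2.99792458e10
ANGSTROM_M = 1e-10
# sqrt(Hartree/(amu A^2)) -> wavenumber (cm^-1)
_FREQ_TO_CM = np.sqrt(HARTREE_J / (AMU_KG * ANGSTROM_M**2)) / (2 * np.pi * C_CM_S)
CM_TO_KELVIN = 1.4387768775039338  # h c / kB * 1 cm^-1, vibrational theta per cm^-1

LINEAR_MOMENT_RATIO = 1e-8
STATIONARY_FORCE_TOL = 1e-3  # Hartree/A; above this, warn that geometry is not stationary


@dataclass
class ThermoResult:
    """Harmonic frequencies and enthalpy decomposition at one temperature."""

    frequencies: np.ndarray          # cm^-1; imaginary modes stored negative
    zpe: float                       # Hartree
    e_elec: float                    # Hartree
    thermal_trans: float
    thermal_rot: float
    thermal_vib: float
    pv_term: float
    enthalpy: float                  # Hartree, total H(T)
    temperature: float

    @property
    def n_imaginary(self) -> int:
        return int(np.sum(self.frequencies < 0))


def is_linear(coordinates: np.ndarray, masses: np.ndarray) -> bool:
    """Linear if the smallest principal moment ratio is below threshold."""
    if coordinates.shape[0] < 3:
        return True
    com = np.average(coordinates, axis=0, weights=masses)
    x = coordinates - com
    inertia = np.zeros((3, 3))
    for m, r in zip(masses, x):
        inertia += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    moments = np.sort(np.abs(np.linalg.eigvalsh(inertia)))
    return moments[0] < LINEAR_MOMENT_RATIO * max(moments[-1], 1e-30)


def _projection_vectors(coordinates: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal translation/rotation vectors in mass-weighted coordinates."""
    n = coordinates.shape[0]
    sq = np.sqrt(masses)
    com = np.average(coordinates, axis=0, weights=masses)
    x = coordinates - com
    vecs = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = sq
        vecs.append(v.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        v = np.cross(x, axis[None, :]) * sq[:, None]
        vecs.append(v.ravel())
    basis = np.array(vecs).T
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def harmonic_frequencies(
    hessian: np.ndarray,
    masses: np.ndarray,
    coordinates: np.ndarray,
    forces: np.ndarray | None = None,
    symmetry_tol: float = 1e-6,
):
    """Vibrational frequencies (cm^-1) and normal modes from a Cartesian Hessian.

    Translations and rotations are projected out; negative Hessian
    eigenvalues are reported as negative (imaginary) frequencies.  When
    ``forces`` are supplied and the geometry is not a stationary point, a
    warning is issued (the numbers then have no physical meaning but remain
    well defined).
    """
    hessian = np.asarray(hessian, dtype=float)
    n = len(masses)
    if hessian.shape != (3 * n, 3 * n):
        raise ValueError(f"Hessian shape {hessian.shape} does not match {n} atoms")
    asym = np.max(np.abs(hessian - hessian.T)) / max(np.max(np.abs(hessian)), 1e-30)
    if asym > symmetry_tol:
        raise ValueError(f"Hessian asymmetry {asym:.2e} exceeds tolerance {symmetry_tol:.0e}")
    if forces is not None and np.max(np.abs(forces)) > STATIONARY_FORCE_TOL:
        warnings.warn(
            f"frequencies computed at a non-stationary geometry "
            f"(max |force| = {np.max(np.abs(forces)):.2e} Hartree/A)",
            stacklevel=2,
        )
    if n == 1:
        return np.array([]), np.zeros((0, 3))

    inv_sq = 1.0 / np.sqrt(np.repeat(masses, 3))
    h_mw = hessian * inv_sq[:, None] * inv_sq[None, :]
    proj = _projection_vectors(np.asarray(coordinates), np.asarray(masses))
    p = np.eye(3 * n) - proj @ proj.T
    h_proj = p @ h_mw @ p
    evals, evecs = np.linalg.eigh(0.5 * (h_proj + h_proj.T))

    n_rigid = proj.shape[1]  # 6, 5 for linear, 3 for diatomic handled by rank
    order = np.argsort(np.abs(evals))
    vib_idx = np.sort(order[n_rigid:])
    lam = evals[vib_idx]
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * _FREQ_TO_CM
    modes = (evecs[:, vib_idx] * inv_sq[:, None]).T.reshape(-1, n, 3)
    return freqs, modes


def enthalpy(
    molecule: Molecule,
    e_elec: float,
    frequencies: np.ndarray,
    temperature: float = 298.15,
    drop_imaginary: bool = False,
) -> ThermoResult:
    """Ideal-gas HO/RR enthalpy H(T) in Hartree.

    H = E_elec + ZPE + 3/2 RT (trans) + RT_rot (3/2 nonlinear, 1 linear,
    0 atom) + sum_modes R theta_v/(exp(theta_v/T)-1) + RT (pV).
    """
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs < 0):
        if not drop_imaginary:
            raise ValueError(
                f"{int(np.sum(freqs < 0))} imaginary frequencies present; "
                "pass drop_imaginary=True to ignore them"
            )
        freqs = freqs[freqs >= 0]
    kt = KB_HARTREE * temperature
    thermal_trans = 1.5 * kt
    if molecule.n_atoms == 1:
        thermal_rot = 0.0
    elif is_linear(molecule.coordinates, molecule.masses):
        thermal_rot = kt
    else:
        thermal_rot = 1.5 * kt
    theta = freqs * CM_TO_KELVIN  # vibrational temperatures, K
    zpe = 0.5 * KB_HARTREE * float(np.sum(theta))
    with np.errstate(over="ignore"):
        occ = np.where(theta / temperature < 500,
                       1.0 / np.expm1(np.minimum(theta / temperature, 500)), 0.0)
    thermal_vib = KB_HARTREE * float(np.sum(theta * occ))
    pv = kt
    total = e_elec + zpe + thermal_trans + thermal_rot + thermal_vib + pv
    return ThermoResult(
        frequencies=np.asarray(frequencies, dtype=float),
        zpe=zpe, e_elec=e_elec,
        thermal_trans=thermal_trans, thermal_rot=thermal_rot,
        thermal_vib=thermal_vib, pv_term=pv,
        enthalpy=total, temperature=temperature,
    )


# ---- heats of formation -------------------------------------------------


@dataclass(frozen=True)
class AtomicEnergyTable:
    """Per-element fitted atomic energies and experimental atomic dHf(298)."""

    atomic_energies: dict[str, float]     # Hartree
    atomic_dhf_exp: dict[str, float]      # kcal/mol


def load_atomic_dhf(path=None) -> dict[str, float]:
    """Experimental atomic heats of formation at 298 K (kcal/mol) from CSV."""
    if path is None:
        source = resources.files("deltapot.data").joinpath("atomic_hof.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = {}
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    for row in csv.DictReader(rows):
        out[row["element"]] = float(row["dhf_exp_kcal"])
    return out


def heat_of_formation(
    molecule: Molecule, h_calc: float, table: AtomicEnergyTable
) -> float:
    """dHf(298) in kcal/mol from the atomization route.

    dHf(M) = sum_A dHf_exp(A) - [sum_A E_A - H_M(298)] with the bracket
    (atomization enthalpy with fitted atomic energies) converted from
    Hartree to kcal/mol.
    """
    s_exp = 0.0
    s_atomic = 0.0
    for e in molecule.elements:
        if e not in table.atomic_energies or e not in table.atomic_dhf_exp:
            raise MoleculeError(f"element {e} missing from atomic energy table")
        s_exp += table.atomic_dhf_exp[e]
        s_atomic += table.atomic_energies[e]
    return s_exp - (s_atomic - h_calc) * HARTREE_TO_KCALMOL


def fit_atomic_energies(
    records: Sequence[tuple[Molecule, float, float]],
    element_order: Sequence[str],
    atomic_dhf_exp: dict[str, float] | None = None,
):
    """Fit per-element atomic energies to experimental heats of formation.

    ``records`` are (molecule, H_calc(298) in Hartree, dHf_exp in kcal/mol).
    dHf_calc is linear in each atomic energy E_A with coefficient
    -n_A * 627.5..., so the fit is ordinary least squares.  Returns
    (AtomicEnergyTable, residuals in kcal/mol, ordered as the records).
    """
    if atomic_dhf_exp is None:
        atomic_dhf_exp = load_atomic_dhf()
    comp = np.array(
        [composition_vector(mol, element_order) for mol, _, _ in records], dtype=float
    )
    rank = np.linalg.matrix_rank(comp)
    if rank < len(element_order):
        _, s, vt = np.linalg.svd(comp)
        null = vt[rank:]
        bad = [element_order[i] for i in range(len(element_order))
               if np.any(np.abs(null[:, i]) > 1e-8)]
        raise MoleculeError(
            f"composition matrix is rank-deficient: atomic energies for {bad} "
            "cannot be determined from this molecule set"
        )
    # dHf_calc,r = c_r - K * sum_A n_rA E_A ; want dHf_calc = dHf_exp
    k = HARTREE_TO_KCALMOL
    c = np.array([
        sum(atomic_dhf_exp[e] for e in mol.elements) + k * h
        for mol, h, _ in records
    ])
    y = c - np.array([d for _, _, d in records])
    sol, *_ = np.linalg.lstsq(k * comp, y, rcond=None)
    table = AtomicEnergyTable(
        {e: float(v) for e, v in zip(element_order, sol)},
        {e: atomic_dhf_exp[e] for e in element_order},
    )
    residuals = np.array([
        heat_of_formation(mol, h, table) - d for mol, h, d in records
    ])
    return table, residuals
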