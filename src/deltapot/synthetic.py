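"""Synthetic study system: toy baseline, planted corrections, conformers.

This module generates everything needed to exercise the full pipeline with
no external data.  The hierarchy of "levels of theory" is emulated as

    low  (baseline) : analytic Morse-bond + soft-repulsion potential,
    mid             : baseline + a planted smooth pair correction
                      (energies and analytic forces, like a DFT reference),
    high            : mid + a second, smaller planted correction
                      (energies only, like a coupled-cluster reference).

Because every correction has a recorded closed form, tests can evaluate the
ground truth independently of anything the networks learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np

from .chem import COVALENT_RADII, LabeledRecord, Molecule, read_xyz
from .composite import hessian as fd_hessian
from .optimize import optimize_geometry
from .thermo import _FREQ_TO_CM, KB_HARTREE, harmonic_frequencies


def load_templates() -> dict[str, Molecule]:
    """The packaged small-molecule templates (H2 ... H2CO), by name."""
    text = resources.files("deltapot.data").joinpath("templates.xyz").read_text()
    mols = read_xyz(text)
    out = {}
    for mol in mols:
        name = dict(
            tok.split("=", 1) for tok in mol.comment.split() if "=" in tok
        ).get("name", f"mol{len(out)}")
        out[name] = mol
    return out


class ToyBaseline:
    """Analytic stand-in for the semiempirical baseline slot.

    Morse potentials act over bonded pairs (pairs closer than
    ``bond_factor`` times the covalent-radius sum of the evaluated
    geometry), a soft exponential repulsion over the remaining pairs.  The
    energy goes to zero at infinite separation and forces are analytic.
    Bond classification is geometric and re-evaluated per call; for
    near-equilibrium conformers it never changes, keeping the potential
    smooth over any sampled dataset.
    """

    name = "toy-morse"

    def __init__(
        self,
        d_e: float = 0.15,          # Hartree, Morse well depth
        a: float = 2.0,             # 1/Angstrom, Morse width
        bond_factor: float = 1.6,
        rep_a: float = 1.0,         # Hartree, nonbonded repulsion amplitude
        rep_rho: float = 0.4,       # Angstrom, repulsion decay length
    ):
        self.d_e = d_e
        self.a = a
        self.bond_factor = bond_factor
        self.rep_a = rep_a
        self.rep_rho = rep_rho

    def morse_r_e(self, e1: str, e2: str) -> float:
        return COVALENT_RADII[e1] + COVALENT_RADII[e2]

    def _terms(self, molecule: Molecule):
        coords = molecule.coordinates
        for i, j in combinations(range(molecule.n_atoms), 2):
            rij = coords[i] - coords[j]
            r = float(np.linalg.norm(rij))
            r_e = self.morse_r_e(molecule.elements[i], molecule.elements[j])
            bonded = r < self.bond_factor * r_e
            yield i, j, r, rij / r, r_e, bonded

    def energy(self, molecule: Molecule) -> float:
        e = 0.0
        for _, _, r, _, r_e, bonded in self._terms(molecule):
            if bonded:
                x = 1.0 - np.exp(-self.a * (r - r_e))
                e += self.d_e * (x * x - 1.0)
            else:
                e += self.rep_a * np.exp(-r / self.rep_rho)
        return e

    def forces(self, molecule: Molecule) -> np.ndarray:
        f = np.zeros_like(molecule.coordinates)
        for i, j, r, u, r_e, bonded in self._terms(molecule):
            if bonded:
                ex = np.exp(-self.a * (r - r_e))
                de_dr = 2.0 * self.d_e * (1.0 - ex) * self.a * ex
            else:
                de_dr = -self.rep_a / self.rep_rho * np.exp(-r / self.rep_rho)
            f[i] -= de_dr * u
            f[j] += de_dr * u
        return f


@dataclass(frozen=True)
class PlantedCorrection:
    """Smooth correction with a recorded closed form.

    energy = sum_{i<j} amplitude * exp(-(r_ij - center)^2 / width^2)
             + sum_atoms offsets[element]

    The linear offsets exercise the SAE centering (they vanish exactly after
    centering); the Gaussian-of-distance part is what the networks must
    actually learn.
    """

    amplitude: float = 0.005        # Hartree
    center: float = 1.4             # Angstrom
    width: float = 0.7              # Angstrom
    offsets: dict = field(default_factory=lambda: {"H": -0.002, "C": 0.004,
                                                   "N": -0.003, "O": 0.001})
    name = "planted-correction"

    def energy(self, molecule: Molecule) -> float:
        e = sum(self.offsets.get(s, 0.0) for s in molecule.elements)
        coords = molecule.coordinates
        for i, j in combinations(range(molecule.n_atoms), 2):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            e += self.amplitude * np.exp(-((r - self.center) / self.width) ** 2)
        return e

    def forces(self, molecule: Molecule) -> np.ndarray:
        f = np.zeros_like(molecule.coordinates)
        coords = molecule.coordinates
        for i, j in combinations(range(molecule.n_atoms), 2):
            rij = coords[i] - coords[j]
            r = float(np.linalg.norm(rij))
            g = self.amplitude * np.exp(-((r - self.center) / self.width) ** 2)
            de_dr = -2.0 * (r - self.center) / self.width**2 * g
            u = rij / r
            f[i] -= de_dr * u
            f[j] += de_dr * u
        return f

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "center": self.center,
                "width": self.width, "offsets": dict(self.offsets)}

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedCorrection":
        return cls(**d)


#: default second-stage ("high" level) correction on top of mid
DEFAULT_HIGH_CORRECTION = PlantedCorrection(
    amplitude=-0.002, center=1.1, width=0.9,
    offsets={"H": 0.0005, "C": -0.001, "N": 0.0008, "O": -0.0004},
)


class SummedPotential:
    """Sum of EnergyProviders (used to label mid/high levels exactly)."""

    def __init__(self, *providers, name: str = "sum"):
        self.providers = providers
        self.name = name

    def energy(self, molecule: Molecule) -> float:
        return sum(p.energy(molecule) for p in self.providers)

    def forces(self, molecule: Molecule) -> np.ndarray:
        out = np.zeros_like(molecule.coordinates)
        for p in self.providers:
            out += p.forces(molecule)
        return out


def normal_mode_sample(
    template: Molecule,
    potential,
    temperature: float = 300.0,
    n: int = 10,
    seed: int = 0,
    fmax: float = 1e-5,
) -> list[Molecule]:
    """Harmonic thermal sampling around the optimized template.

    The template is relaxed on ``potential``; normal-mode amplitudes are
    drawn from zero-mean normals with the classical-thermal variance
    kT / lambda_m (lambda_m the mass-weighted Hessian eigenvalue), so the
    per-mode displacement variance follows a 1/omega^2 law at fixed T.
    Deterministic for a given seed.
    """
    opt = optimize_geometry(template, potential, fmax=fmax, max_steps=1000)
    if not opt.converged:
        raise RuntimeError(f"template optimization did not converge: {opt.message}")
    mol0 = opt.molecule
    rng = np.random.default_rng(seed)
    if temperature == 0.0 or mol0.n_atoms == 1:
        return [mol0] * n
    hess = fd_hessian(mol0, potential, step=0.005)
    freqs, modes = harmonic_frequencies(hess, mol0.masses, mol0.coordinates)
    if np.any(freqs < -5.0):
        raise RuntimeError(
            f"imaginary modes at the optimized template: {freqs[freqs < -5.0]} cm^-1"
        )
    keep = freqs > 5.0
    lam = (freqs[keep] / _FREQ_TO_CM) ** 2          # Hartree / (amu A^2)
    sigma = np.sqrt(KB_HARTREE * temperature / lam)  # amu^1/2 A
    out = []
    for _ in range(n):
        q = rng.normal(size=lam.shape) * sigma
        disp = np.einsum("m,mak->ak", q, modes[keep])
        out.append(mol0.with_coordinates(mol0.coordinates + disp))
    return out


def label_molecules(
    molecules,
    potential,
    with_forces: bool = True,
    level_tag: str = "mid",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[LabeledRecord]:
    """Attach reference labels from ``potential`` to a list of geometries."""
    rng = np.random.default_rng(seed)
    records = []
    for mol in molecules:
        e = potential.energy(mol)
        if noise_sigma > 0:
            e += rng.normal(scale=noise_sigma)
        f = potential.forces(mol) if with_forces else None
        records.append(LabeledRecord(mol, e, f, level_tag=level_tag))
    return records


def make_delta_dataset(
    templates,
    baseline,
    correction: PlantedCorrection,
    n_per_template: int = 10,
    seed: int = 0,
    with_forces: bool = True,
    noise_sigma: float = 0.0,
    temperature: float = 300.0,
) -> list[LabeledRecord]:
    """Mid-level training records: E = baseline + correction (+ optional noise)."""
    mid = SummedPotential(baseline, correction, name="mid")
    records = []
    for t, template in enumerate(templates):
        mols = normal_mode_sample(
            template, baseline, temperature=temperature, n=n_per_template,
            seed=_subseed(seed, t),
        )
        records.extend(label_molecules(
            mols, mid, with_forces=with_forces, level_tag="mid",
            noise_sigma=noise_sigma, seed=_subseed(seed, 10_000 + t),
        ))
    return records


def make_two_level_dataset(
    templates,
    baseline,
    correction: PlantedCorrection,
    high_correction: PlantedCorrection = DEFAULT_HIGH_CORRECTION,
    n_per_template: int = 10,
    seed: int = 0,
    temperature: float = 300.0,
):
    """(mid records with forces, high records energy-only) on shared geometries."""
    mid_pot = SummedPotential(baseline, correction, name="mid")
    high_pot = SummedPotential(baseline, correction, high_correction, name="high")
    mid, high = [], []
    for t, template in enumerate(templates):
        mols = normal_mode_sample(
            template, baseline, temperature=temperature, n=n_per_template,
            seed=_subseed(seed, t),
        )
        mid.extend(label_molecules(mols, mid_pot, with_forces=True, level_tag="mid"))
        high.extend(label_molecules(mols, high_pot, with_forces=False, level_tag="high"))
    return mid, high


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
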