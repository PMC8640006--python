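"""Geometry optimization of any EnergyProvider by BFGS in Cartesians.

Convergence is on the maximum absolute force component (Hartree/Angstrom),
which maps directly onto the infinity-norm gradient test of scipy's BFGS.
No symmetry constraints are imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .chem import Molecule

DEFAULT_FMAX = 4.5e-4  # Hartree/Angstrom
DEFAULT_MAX_STEPS = 500


@dataclass
class OptResult:
    """Outcome of a geometry optimization."""

    molecule: Molecule
    energy: float
    fmax: float                      # max |force component| at the final geometry
    frms: float
    converged: bool
    n_iterations: int
    trajectory: list[Molecule] = field(default_factory=list)
    message: str = ""


def optimize_geometry(
    molecule: Molecule,
    potential,
    fmax: float = DEFAULT_FMAX,
    max_steps: int = DEFAULT_MAX_STEPS,
    keep_trajectory: bool = False,
) -> OptResult:
    """Minimize the potential energy; returns a non-converged result (not an
    exception) when the step budget is exhausted."""
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    shape = molecule.coordinates.shape
    trajectory: list[Molecule] = []

    def fun(x):
        mol = molecule.with_coordinates(x.reshape(shape))
        e = potential.energy(mol)
        g = -potential.forces(mol).ravel()
        return e, g

    def callback(x):
        if keep_trajectory:
            trajectory.append(molecule.with_coordinates(x.reshape(shape).copy()))

    res = minimize(
        fun, molecule.coordinates.ravel(), jac=True, method="BFGS",
        callback=callback,
        options={"gtol": fmax, "maxiter": max_steps, "norm": np.inf},
    )
    final = molecule.with_coordinates(res.x.reshape(shape))
    forces = -res.jac.reshape(shape)
    max_f = float(np.max(np.abs(forces)))
    return OptResult(
        molecule=final,
        energy=float(res.fun),
        fmax=max_f,
        frms=float(np.sqrt(np.mean(forces**2))),
        converged=bool(max_f <= fmax),
        n_iterations=int(res.nit),
        trajectory=trajectory,
        message=res.message,
    )
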