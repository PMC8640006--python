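"""Composite potential: baseline + neural correction + dispersion.

The total energy is the plain sum of three independently evaluable
components over a pluggable baseline.  Forces are component-wise analytic;
Hessians are central finite differences of the analytic forces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .chem import Molecule
from .dispersion import DispersionParams, dispersion_total
from .nnpot import ModelEnsemble


@runtime_checkable
class EnergyProvider(Protocol):
    """Contract for any energy component: energy in Hartree, forces in Hartree/A."""

    name: str

    def energy(self, molecule: Molecule) -> float: ...

    def forces(self, molecule: Molecule) -> np.ndarray: ...


class ZeroBaseline:
    """Baseline that contributes nothing (pure NN + dispersion operation)."""

    name = "zero"

    def energy(self, molecule: Molecule) -> float:
        return 0.0

    def forces(self, molecule: Molecule) -> np.ndarray:
        return np.zeros_like(molecule.coordinates)


class FunctionProvider:
    """Adapter wrapping plain callables as an EnergyProvider."""

    def __init__(self, name: str, energy_fn: Callable, forces_fn: Callable | None = None):
        self.name = name
        self._energy = energy_fn
        self._forces = forces_fn

    def energy(self, molecule: Molecule) -> float:
        return float(self._energy(molecule))

    def forces(self, molecule: Molecule) -> np.ndarray:
        if self._forces is not None:
            return np.asarray(self._forces(molecule))
        return numerical_forces(self, molecule)


class DispersionProvider:
    """Dispersion term packaged as an EnergyProvider component."""

    name = "dispersion"

    def __init__(self, params: DispersionParams):
        self.params = params

    def energy(self, molecule: Molecule) -> float:
        e, _, _ = dispersion_total(molecule, self.params)
        return e

    def forces(self, molecule: Molecule) -> np.ndarray:
        _, grad, _ = dispersion_total(molecule, self.params)
        return -grad


def numerical_forces(provider, molecule: Molecule, step: float = 1e-4) -> np.ndarray:
    """Central-difference forces of any provider's energy."""
    coords = molecule.coordinates
    forces = np.zeros_like(coords)
    for a in range(molecule.n_atoms):
        for k in range(3):
            cp = coords.copy(); cp[a, k] += step
            cm = coords.copy(); cm[a, k] -= step
            ep = provider.energy(molecule.with_coordinates(cp))
            em = provider.energy(molecule.with_coordinates(cm))
            forces[a, k] = -(ep - em) / (2 * step)
    return forces


def check_provider_forces(
    provider, molecule: Molecule, rtol: float = 1e-5, atol: float = 1e-6
) -> float:
    """Validate a provider's forces against its own energy.

    Passes when max|analytic - numeric| <= atol + rtol * max|numeric|; the
    absolute floor absorbs finite-difference noise at near-stationary
    geometries.  Returns the max absolute deviation (Hartree/Angstrom).
    """
    analytic = provider.forces(molecule)
    numeric = numerical_forces(provider, molecule)
    err = float(np.max(np.abs(analytic - numeric)))
    bound = atol + rtol * float(np.max(np.abs(numeric)))
    if err > bound:
        raise ValueError(
            f"provider {provider.name!r}: forces disagree with its energy "
            f"(max deviation {err:.2e} > {bound:.2e})"
        )
    return err


@dataclass
class CompositeResult:
    """Per-component breakdown of one composite evaluation."""

    energy: float
    baseline: float
    nn: float
    dispersion: float
    nn_spread: float = 0.0
    forces: np.ndarray | None = None
    component_forces: dict | None = None


class CompositePotential:
    """E_total = E_baseline + E_NN + E_disp over a pluggable baseline.

    Any component may be None / disabled; disabled components contribute
    exactly zero to energy and forces.
    """

    name = "composite"

    def __init__(
        self,
        baseline: EnergyProvider | None = None,
        ensemble: ModelEnsemble | None = None,
        dispersion: DispersionParams | None = None,
    ):
        self.baseline = baseline or ZeroBaseline()
        self.ensemble = ensemble
        self.dispersion = DispersionProvider(dispersion) if dispersion else None

    def evaluate(self, molecule: Molecule, forces: bool = False) -> CompositeResult:
        def _component(name, fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"component {name!r} failed: {exc}") from exc

        e_base = _component(self.baseline.name, lambda: self.baseline.energy(molecule))
        spread = 0.0
        if self.ensemble is not None:
            e_nn, _, spread = _component("nn", lambda: self.ensemble.energy(molecule))
        else:
            e_nn = 0.0
        e_disp = (_component("dispersion", lambda: self.dispersion.energy(molecule))
                  if self.dispersion else 0.0)
        result = CompositeResult(
            energy=e_base + e_nn + e_disp,
            baseline=e_base, nn=e_nn, dispersion=e_disp, nn_spread=spread,
        )
        if forces:
            comp = {"baseline": self.baseline.forces(molecule)}
            comp["nn"] = (self.ensemble.forces(molecule) if self.ensemble is not None
                          else np.zeros_like(molecule.coordinates))
            comp["dispersion"] = (self.dispersion.forces(molecule) if self.dispersion
                                  else np.zeros_like(molecule.coordinates))
            result.component_forces = comp
            result.forces = comp["baseline"] + comp["nn"] + comp["dispersion"]
        return result

    # EnergyProvider interface, so composites nest / feed the optimizer
    def energy(self, molecule: Molecule) -> float:
        return self.evaluate(molecule).energy

    def forces(self, molecule: Molecule) -> np.ndarray:
        return self.evaluate(molecule, forces=True).forces


def total_energy(
    molecule: Molecule,
    baseline: EnergyProvider | None = None,
    ensemble: ModelEnsemble | None = None,
    dispersion: DispersionParams | None = None,
) -> CompositeResult:
    return CompositePotential(baseline, ensemble, dispersion).evaluate(molecule)


def total_forces(
    molecule: Molecule,
    baseline: EnergyProvider | None = None,
    ensemble: ModelEnsemble | None = None,
    dispersion: DispersionParams | None = None,
) -> np.ndarray:
    return CompositePotential(baseline, ensemble, dispersion).forces(molecule)


def hessian(molecule: Molecule, potential, step: float = 0.005) -> np.ndarray:
    """Cartesian Hessian (3N x 3N, Hartree/A^2) by central differences of forces.

    Symmetrized as (H + H^T)/2; ``potential`` is any EnergyProvider with
    analytic (or at least smooth) forces.
    """
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    n = molecule.n_atoms
    coords = molecule.coordinates
    h = np.zeros((3 * n, 3 * n))
    for a in range(n):
        for k in range(3):
            cp = coords.copy(); cp[a, k] += step
            cm = coords.copy(); cm[a, k] -= step
            fp = potential.forces(molecule.with_coordinates(cp))
            fm = potential.forces(molecule.with_coordinates(cm))
            # H = d^2 E / dR^2 = -dF/dR
            h[3 * a + k, :] = -(fp - fm).ravel() / (2 * step)
    return 0.5 * (h + h.T)
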