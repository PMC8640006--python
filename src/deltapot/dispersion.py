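"""London dispersion: damped pairwise C6/C8 plus Axilrod-Teller-Muto term.

A generic D3(BJ)-style form: the two-body energy uses rational
(Becke-Johnson) damping,

    E_2 = - sum_{i<j} sum_{n in 6,8} s_n C_n^ij / (r_ij^n + (a1 R0_ij + a2)^n),

and the three-body term is the triple-dipole ATM energy

    E_ATM = s9 sum_{i<j<k} C9_ijk (3 cos t_i cos t_j cos t_k + 1) / (r_ij r_jk r_ki)^3,

undamped by default, with an optional BJ-style switch.  Per-element-pair
coefficients ship as an editable table for H/C/N/O; an external provider
implementing the EnergyProvider contract can replace this module wholesale.
All energies in Hartree, distances in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .chem import Molecule, MoleculeError

# Free-atom-like C6 coefficients (Hartree * Angstrom^6; e.g. C6(H,H) ~ 6.5
# a.u. = 0.14 in these units) and critical radii R0 (Angstrom) for the
# packaged H/C/N/O table.  Generic literature-magnitude values for a
# standalone dispersion term; a production calculation would slot in an
# external dispersion provider instead.
_DEFAULT_C6 = {"H": 0.14, "C": 1.02, "N": 0.53, "O": 0.34}
_DEFAULT_R0 = {"H": 1.40, "C": 1.90, "N": 1.80, "O": 1.70}


@dataclass(frozen=True)
class DispersionParams:
    """Coefficients and damping constants of the dispersion model."""

    c6: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_C6))
    r0: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_R0))
    s6: float = 1.0
    s8: float = 0.8
    s9: float = 1.0
    a1: float = 0.45
    a2: float = 2.50
    c8_ratio: float = 2.0  # C8_ij = c8_ratio * C6_ij * R0_ij^2
    atm_damping: str = "none"  # "none" (zero-damping) or "bj" (rational)
    enable_two_body: bool = True
    enable_three_body: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.c6.values()):
            raise ValueError("C6 coefficients must be non-negative")
        if any(v <= 0 for v in self.r0.values()):
            raise ValueError("damping radii must be positive")

    def pair_c6(self, e1: str, e2: str) -> float:
        try:
            return float(np.sqrt(self.c6[e1] * self.c6[e2]))
        except KeyError as exc:
            raise MoleculeError(f"no dispersion parameters for element {exc.args[0]}")

    def pair_r0(self, e1: str, e2: str) -> float:
        return 0.5 * (self.r0[e1] + self.r0[e2])

    def pair_c8(self, e1: str, e2: str) -> float:
        return self.c8_ratio * self.pair_c6(e1, e2) * self.pair_r0(e1, e2) ** 2

    def triple_c9(self, e1: str, e2: str, e3: str) -> float:
        # geometric-mean combination rule over the three pair C6 values
        return float(np.sqrt(
            self.pair_c6(e1, e2) * self.pair_c6(e2, e3) * self.pair_c6(e3, e1)
        ))

    def to_dict(self) -> dict:
        return {
            "c6": dict(self.c6), "r0": dict(self.r0),
            "s6": self.s6, "s8": self.s8, "s9": self.s9,
            "a1": self.a1, "a2": self.a2, "c8_ratio": self.c8_ratio,
            "atm_damping": self.atm_damping,
            "enable_two_body": self.enable_two_body,
            "enable_three_body": self.enable_three_body,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DispersionParams":
        return cls(**d)


def two_body_dispersion(molecule: Molecule, params: DispersionParams):
    """BJ-damped pairwise energy and its gradient dE/dR (Hartree, Hartree/A)."""
    n = molecule.n_atoms
    coords = molecule.coordinates
    energy = 0.0
    grad = np.zeros((n, 3))
    for i, j in combinations(range(n), 2):
        ei, ej = molecule.elements[i], molecule.elements[j]
        rij = coords[i] - coords[j]
        r = float(np.linalg.norm(rij))
        c6 = params.pair_c6(ei, ej)
        c8 = params.pair_c8(ei, ej)
        damp = params.a1 * params.pair_r0(ei, ej) + params.a2
        de_dr = 0.0
        for s_n, c_n, p in ((params.s6, c6, 6), (params.s8, c8, 8)):
            denom = r ** p + damp ** p
            energy -= s_n * c_n / denom
            de_dr += s_n * c_n * p * r ** (p - 1) / denom ** 2
        u = rij / r
        grad[i] += de_dr * u
        grad[j] -= de_dr * u
    return energy, grad


def atm_three_body(molecule: Molecule, params: DispersionParams):
    """Axilrod-Teller-Muto triple-dipole energy and gradient.

    Fewer than three atoms contribute exactly zero.  The default is
    zero-damping; with ``a1``/``a2`` BJ-style damping the product of pair
    distances in the denominator is shifted (optional switch not applied
    here — geometry-independent coefficients keep the term analytic).
    """
    n = molecule.n_atoms
    coords = molecule.coordinates
    grad = np.zeros((n, 3))
    if n < 3:
        return 0.0, grad
    energy = 0.0
    for i, j, k in combinations(range(n), 3):
        ei, ej, ek = (molecule.elements[t] for t in (i, j, k))
        c9 = params.triple_c9(ei, ej, ek)
        if params.atm_damping == "bj":
            damp = (params.a1 * params.pair_r0(ei, ej) + params.a2,
                    params.a1 * params.pair_r0(ej, ek) + params.a2,
                    params.a1 * params.pair_r0(ek, ei) + params.a2)
        else:
            damp = (0.0, 0.0, 0.0)
        e, (dea, deb, dec) = _atm_triple(coords[i], coords[j], coords[k], c9, damp)
        energy += params.s9 * e
        # a = |ri-rj|, b = |rj-rk|, c = |rk-ri|
        a = np.linalg.norm(coords[i] - coords[j])
        b = np.linalg.norm(coords[j] - coords[k])
        c = np.linalg.norm(coords[k] - coords[i])
        ua = (coords[i] - coords[j]) / a
        ub = (coords[j] - coords[k]) / b
        uc = (coords[k] - coords[i]) / c
        grad[i] += params.s9 * (dea * ua - dec * uc)
        grad[j] += params.s9 * (deb * ub - dea * ua)
        grad[k] += params.s9 * (dec * uc - deb * ub)
    return energy, grad


def _atm_triple(ri, rj, rk, c9: float, damp=(0.0, 0.0, 0.0)):
    """ATM energy of one triple and partials w.r.t. the three distances.

    The angular factor reduces, via the law of cosines, to a rational
    function of the squared distances A=a^2, B=b^2, C=c^2:
    3 cos t_i cos t_j cos t_k + 1 = 3 N / (8 A B C) + 1 with
    N = (A+C-B)(A+B-C)(B+C-A).  The denominator is the product of
    (r_p^3 + d_p^3) over the three pairs; d_p = 0 recovers zero-damping,
    d_p = a1 R0_p + a2 gives the rational (BJ-style) switch.
    """
    a = float(np.linalg.norm(ri - rj))
    b = float(np.linalg.norm(rj - rk))
    c = float(np.linalg.norm(rk - ri))
    A, B, C = a * a, b * b, c * c
    f1, f2, f3 = A + C - B, A + B - C, B + C - A
    N = f1 * f2 * f3
    dN_dA = f2 * f3 + f1 * f3 - f1 * f2
    dN_dB = -f2 * f3 + f1 * f3 + f1 * f2
    dN_dC = f2 * f3 - f1 * f3 + f1 * f2
    da3, db3, dc3 = (d ** 3 for d in damp)
    denom_a, denom_b, denom_c = a ** 3 + da3, b ** 3 + db3, c ** 3 + dc3
    denom = denom_a * denom_b * denom_c
    abc = A * B * C
    ang = 3.0 * N / (8.0 * abc) + 1.0
    e = c9 * ang / denom

    def d_ang(r, dn):
        # d(ang)/dr with dA/da = 2a etc.
        return 3.0 / 8.0 * 2.0 * r / abc * (dn - N / (r * r))

    dea = c9 * (d_ang(a, dN_dA) / denom - ang * 3.0 * a * a / (denom_a * denom))
    deb = c9 * (d_ang(b, dN_dB) / denom - ang * 3.0 * b * b / (denom_b * denom))
    dec = c9 * (d_ang(c, dN_dC) / denom - ang * 3.0 * c * c / (denom_c * denom))
    return e, (dea, deb, dec)


def dispersion_total(molecule: Molecule, params: DispersionParams):
    """E_disp = E_2 + E_ATM with gradient; disabled terms contribute zero."""
    n = molecule.n_atoms
    e2, g2 = (0.0, np.zeros((n, 3)))
    e3, g3 = (0.0, np.zeros((n, 3)))
    if params.enable_two_body:
        e2, g2 = two_body_dispersion(molecule, params)
    if params.enable_three_body:
        e3, g3 = atm_three_body(molecule, params)
    return e2 + e3, g2 + g3, {"two_body": e2, "three_body": e3}
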