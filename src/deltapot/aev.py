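"""Atomic environment vectors (AEVs): radial + angular symmetry functions.

The descriptor follows the classic ANI construction — Gaussian radial shells
under a cosine cutoff, and a modified angular term over unordered neighbor
pairs — with an enlarged 4 Angstrom angular cutoff for better long-range
description.  Feature layout: per-element radial blocks first, then
per-element-pair angular blocks (sorted element pairs), each angular block
ordered shell-major over angle sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import DEFAULT_ELEMENTS, Molecule, MoleculeError


@dataclass(frozen=True)
class AEVParams:
    """Hyperparameters of the symmetry-function descriptor.

    Defaults are classic ANI-style choices with the angular cutoff raised to
    4.0 Angstrom; every value is overridable through configuration.
    """

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    radial_cutoff: float = 5.2
    angular_cutoff: float = 4.0
    eta_radial: float = 16.0
    n_radial_shells: int = 16
    eta_angular: float = 8.0
    n_angular_shells: int = 4
    n_theta: int = 8
    zeta: float = 32.0
    min_distance: float = 0.1
    radial_shifts: tuple[float, ...] = ()
    angular_shifts: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.angular_cutoff > self.radial_cutoff:
            raise ValueError("angular cutoff must not exceed radial cutoff")
        if not self.radial_shifts:
            object.__setattr__(
                self,
                "radial_shifts",
                tuple(np.linspace(0.8, self.radial_cutoff, self.n_radial_shells, endpoint=False)),
            )
        if not self.angular_shifts:
            object.__setattr__(
                self,
                "angular_shifts",
                tuple(np.linspace(0.8, self.angular_cutoff, self.n_angular_shells, endpoint=False)),
            )
        object.__setattr__(self, "elements", tuple(self.elements))
        if max(self.radial_shifts) >= self.radial_cutoff:
            raise ValueError("radial shell centers must lie below the radial cutoff")
        if max(self.angular_shifts) >= self.angular_cutoff:
            raise ValueError("angular shell centers must lie below the angular cutoff")

    @property
    def theta_sections(self) -> np.ndarray:
        n = self.n_theta
        return (np.arange(n) + 0.5) * np.pi / n

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_pairs(self) -> int:
        n = self.n_elements
        return n * (n + 1) // 2

    @property
    def radial_length(self) -> int:
        return self.n_elements * len(self.radial_shifts)

    @property
    def angular_length(self) -> int:
        return self.n_pairs * len(self.angular_shifts) * self.n_theta

    @property
    def feature_length(self) -> int:
        return self.radial_length + self.angular_length

    def element_index(self, symbol: str) -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            raise MoleculeError(f"element {symbol} not in descriptor set {self.elements}")

    def pair_index(self, e1: int, e2: int) -> int:
        a, b = min(e1, e2), max(e1, e2)
        n = self.n_elements
        # index in the enumeration (0,0),(0,1)..(0,n-1),(1,1),..
        return a * n - a * (a - 1) // 2 + (b - a)

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "radial_cutoff": self.radial_cutoff,
            "angular_cutoff": self.angular_cutoff,
            "eta_radial": self.eta_radial,
            "eta_angular": self.eta_angular,
            "n_theta": self.n_theta,
            "zeta": self.zeta,
            "min_distance": self.min_distance,
            "radial_shifts": [float(x) for x in self.radial_shifts],
            "angular_shifts": [float(x) for x in self.angular_shifts],
            "n_radial_shells": len(self.radial_shifts),
            "n_angular_shells": len(self.angular_shifts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AEVParams":
        d = dict(d)
        d["elements"] = tuple(d["elements"])
        d["radial_shifts"] = tuple(d.get("radial_shifts", ()))
        d["angular_shifts"] = tuple(d.get("angular_shifts", ()))
        return cls(**d)


@dataclass
class AEVDescriptor:
    """Per-atom feature matrix plus the element of each atom."""

    features: np.ndarray  # N x F
    elements: tuple[str, ...]


def cutoff_fn(r, rc: float):
    """Cosine cutoff: 1 at r=0, 0 at r>=rc, C1-smooth at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative distance passed to cutoff function")
    out = np.where(r < rc, 0.5 * np.cos(np.pi * np.minimum(r, rc) / rc) + 0.5, 0.0)
    return out if out.ndim else float(out)


def _cutoff_and_deriv(r: np.ndarray, rc: float):
    inside = r < rc
    x = np.pi * r / rc
    f = np.where(inside, 0.5 * np.cos(x) + 0.5, 0.0)
    df = np.where(inside, -0.5 * np.pi / rc * np.sin(x), 0.0)
    return f, df


def compute_aev(molecule: Molecule, params: AEVParams, jacobian: bool = False):
    """Compute AEVs; optionally also the Jacobian d feature / d coordinate.

    Returns ``AEVDescriptor`` or ``(AEVDescriptor, J)`` with
    ``J[i, f, a, k] = d features[i, f] / d R[a, k]``.
    """
    n = molecule.n_atoms
    coords = molecule.coordinates
    nf = params.feature_length
    feats = np.zeros((n, nf))
    jac = np.zeros((n, nf, n, 3)) if jacobian else None
    el_idx = np.array([params.element_index(e) for e in molecule.elements])

    if n > 1:
        dmat = molecule.distance_matrix()
        off = ~np.eye(n, dtype=bool)
        if np.any(dmat[off] < params.min_distance):
            i, j = np.unravel_index(np.argmin(dmat + np.eye(n) * 1e9), dmat.shape)
            raise MoleculeError(
                f"degenerate geometry: atoms {i} and {j} are {dmat[i, j]:.4f} A apart "
                f"(minimum {params.min_distance} A)"
            )
        _radial_part(coords, el_idx, dmat, params, feats, jac)
        _angular_part(coords, el_idx, dmat, params, feats, jac)

    desc = AEVDescriptor(feats, molecule.elements)
    return (desc, jac) if jacobian else desc


def _radial_part(coords, el_idx, dmat, params, feats, jac):
    n = coords.shape[0]
    rs = np.asarray(params.radial_shifts)
    nrs = len(rs)
    eta = params.eta_radial
    rc = params.radial_cutoff
    ii, jj = np.nonzero((dmat < rc) & ~np.eye(n, dtype=bool))
    if len(ii) == 0:
        return
    r = dmat[ii, jj]
    fc, dfc = _cutoff_and_deriv(r, rc)
    gauss = np.exp(-eta * (r[:, None] - rs[None, :]) ** 2)  # (m, nrs)
    g = gauss * fc[:, None]
    cols = el_idx[jj][:, None] * nrs + np.arange(nrs)[None, :]
    np.add.at(feats, (ii[:, None], cols), g)
    if jac is not None:
        dg = (-2.0 * eta * (r[:, None] - rs[None, :]) * gauss * fc[:, None]
              + gauss * dfc[:, None])  # d g / d r
        u = (coords[ii] - coords[jj]) / r[:, None]  # d r / d R_i
        # d feat[i, col] / d R_i = dg * u ; / d R_j = -dg * u
        contrib = dg[:, :, None] * u[:, None, :]  # (m, nrs, 3)
        np.add.at(jac, (ii[:, None], cols, ii[:, None]), contrib)
        np.add.at(jac, (ii[:, None], cols, jj[:, None]), -contrib)


def _angular_part(coords, el_idx, dmat, params, feats, jac):
    n = coords.shape[0]
    if n < 3:
        return
    rca = params.angular_cutoff
    rs = np.asarray(params.angular_shifts)
    nas, nth = len(rs), params.n_theta
    theta_s = params.theta_sections
    eta, zeta = params.eta_angular, params.zeta
    ang_off = params.radial_length
    block = nas * nth

    # triplets: center i with unordered neighbor pair (j, k), j < k
    centers, js, ks = [], [], []
    for i in range(n):
        nb = np.nonzero((dmat[i] < rca) & (np.arange(n) != i))[0]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                centers.append(i); js.append(nb[a]); ks.append(nb[b])
    if not centers:
        return
    ci = np.array(centers); jj = np.array(js); kk = np.array(ks)

    v1 = coords[jj] - coords[ci]
    v2 = coords[kk] - coords[ci]
    r1 = dmat[ci, jj]
    r2 = dmat[ci, kk]
    cosT = np.sum(v1 * v2, axis=1) / (r1 * r2)
    cosT = np.clip(cosT, -1.0 + 1e-12, 1.0 - 1e-12)
    theta = np.arccos(cosT)

    fc1, dfc1 = _cutoff_and_deriv(r1, rca)
    fc2, dfc2 = _cutoff_and_deriv(r2, rca)
    m = 0.5 * (r1 + r2)
    gauss = np.exp(-eta * (m[:, None] - rs[None, :]) ** 2)  # (t, nas)
    cosfac = 1.0 + np.cos(theta[:, None] - theta_s[None, :])  # (t, nth)
    angfac = 2.0 ** (1.0 - zeta) * cosfac ** zeta

    pref = gauss[:, :, None] * angfac[:, None, :]  # (t, nas, nth)
    val = pref * (fc1 * fc2)[:, None, None]

    pcol = np.array([params.pair_index(a, b) for a, b in zip(el_idx[jj], el_idx[kk])])
    cols = (ang_off + pcol[:, None] * block
            + (np.arange(nas)[:, None] * nth + np.arange(nth)[None, :]).ravel()[None, :])
    np.add.at(feats, (ci[:, None], cols), val.reshape(len(ci), block))

    if jac is None:
        return

    # derivative pieces
    dgauss_dm = -2.0 * eta * (m[:, None] - rs[None, :]) * gauss  # (t, nas)
    dang_dtheta = (2.0 ** (1.0 - zeta) * zeta * cosfac ** (zeta - 1.0)
                   * (-np.sin(theta[:, None] - theta_s[None, :])))  # (t, nth)

    u1 = v1 / r1[:, None]
    u2 = v2 / r2[:, None]
    sinT = np.sqrt(1.0 - cosT ** 2)
    # d theta / d v1 and / d v2 (theta = arccos c)
    dc_dv1 = (u2 - cosT[:, None] * u1) / r1[:, None]
    dc_dv2 = (u1 - cosT[:, None] * u2) / r2[:, None]
    dth_dv1 = -dc_dv1 / sinT[:, None]
    dth_dv2 = -dc_dv2 / sinT[:, None]

    # chain rule, per derivative channel d in {r1, r2, theta}
    # val = gauss(m) * ang(theta) * fc1(r1) * fc2(r2)
    A = gauss[:, :, None] * angfac[:, None, :]
    dval_dr1 = (0.5 * dgauss_dm[:, :, None] * angfac[:, None, :] * (fc1 * fc2)[:, None, None]
                + A * (dfc1 * fc2)[:, None, None])
    dval_dr2 = (0.5 * dgauss_dm[:, :, None] * angfac[:, None, :] * (fc1 * fc2)[:, None, None]
                + A * (fc1 * dfc2)[:, None, None])
    dval_dth = gauss[:, :, None] * dang_dtheta[:, None, :] * (fc1 * fc2)[:, None, None]

    t = len(ci)
    dval_dr1 = dval_dr1.reshape(t, block)
    dval_dr2 = dval_dr2.reshape(t, block)
    dval_dth = dval_dth.reshape(t, block)

    # dR_j = dval_dr1 * u1 + dval_dth * dth_dv1 ; dR_k analogous; dR_i = -(sum)
    dj = dval_dr1[:, :, None] * u1[:, None, :] + dval_dth[:, :, None] * dth_dv1[:, None, :]
    dk = dval_dr2[:, :, None] * u2[:, None, :] + dval_dth[:, :, None] * dth_dv2[:, None, :]
    di = -(dj + dk)
    np.add.at(jac, (ci[:, None], cols, jj[:, None]), dj)
    np.add.at(jac, (ci[:, None], cols, kk[:, None]), dk)
    np.add.at(jac, (ci[:, None], cols, ci[:, None]), di)


def aev_jacobian(molecule: Molecule, params: AEVParams) -> np.ndarray:
    """Jacobian ``J[i, f, a, k] = d AEV[i, f] / d R[a, k]``."""
    _, jac = compute_aev(molecule, params, jacobian=True)
    return jac
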