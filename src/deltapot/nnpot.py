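"""Per-element feed-forward networks, SAE centering, and ensemble aggregation.

Each supported element owns a small MLP (GELU activations, scalar output)
that maps an atom's AEV row to an atomic energy contribution; a molecule's
neural energy is the sum of atomic contributions plus element-wise linear
offsets (the SAE table, fit by least squares to composition).  An ensemble
averages several independently initialized members and reports their spread
as an uncertainty diagnostic.

The networks are implemented directly on numpy.  Besides the usual forward
and parameter-gradient passes, `param_grads` supports a second-order pass
(gradient of the input-gradient with respect to the weights), which the
training module needs for the force part of the loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .aev import AEVDescriptor, AEVParams, compute_aev
from .chem import LabeledRecord, Molecule, MoleculeError, composition_vector

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)

DEFAULT_HIDDEN = (160, 128, 96)


def gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _phi(x):
    return _INV_SQRT2PI * np.exp(-0.5 * x * x)


def gelu_d1(x):
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _phi(x)


def gelu_d2(x):
    return _phi(x) * (2.0 - x * x)


class ElementNetwork:
    """MLP with GELU hidden layers and a linear scalar output."""

    def __init__(self, element: str, layer_sizes: Sequence[int], rng: np.random.Generator):
        self.element = element
        self.layer_sizes = tuple(layer_sizes)
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer must be scalar")
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            # fan-in-scaled init keeps pre-activations O(1) at any width
            self.weights.append(rng.normal(scale=1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_hidden(self) -> int:
        return len(self.weights) - 1

    def copy(self) -> "ElementNetwork":
        new = ElementNetwork.__new__(ElementNetwork)
        new.element = self.element
        new.layer_sizes = self.layer_sizes
        new.weights = [w.copy() for w in self.weights]
        new.biases = [b.copy() for b in self.biases]
        return new

    def forward(self, x: np.ndarray):
        """Atomic energies for a batch of AEV rows; returns (out, cache)."""
        if x.shape[1] != self.layer_sizes[0]:
            raise MoleculeError(
                f"AEV length {x.shape[1]} does not match network input {self.layer_sizes[0]}"
            )
        a = x
        zs, acts = [], [x]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ w + b
            zs.append(z)
            a = gelu(z)
            acts.append(a)
        out = (a @ self.weights[-1] + self.biases[-1])[:, 0]
        return out, (zs, acts)

    def input_grad(self, cache):
        """d out_i / d x_i for every row i of the batch (n x F)."""
        zs, acts = cache
        d = np.broadcast_to(self.weights[-1][:, 0], (acts[-1].shape[0], self.weights[-1].shape[0]))
        for z, w in zip(reversed(zs), reversed(self.weights[:-1])):
            d = (d * gelu_d1(z)) @ w.T
        return d

    def param_grads(self, cache, out_bar: np.ndarray, v: np.ndarray | None = None):
        """Gradients of S = sum_i out_bar_i * out_i [+ sum_i v_i . g_i] w.r.t. weights.

        ``g_i`` is the input gradient of row i; the optional second term is
        the second-order pass used by force-loss training (``v`` carries all
        scaling).  Returns lists (dW, db) aligned with self.weights/biases.
        """
        zs, acts = cache
        n = acts[0].shape[0]
        L = len(self.weights)
        with_v = v is not None

        if with_v:
            ts, us = [v], []
            t = v
            for z, w in zip(zs, self.weights[:-1]):
                u = t @ w
                t = gelu_d1(z) * u
                us.append(u)
                ts.append(t)

        dWs = [None] * L
        dbs = [None] * L
        ob = out_bar[:, None]
        dWs[-1] = acts[-1].T @ ob
        dbs[-1] = ob.sum(axis=0)
        a_bar = ob @ self.weights[-1].T
        if with_v:
            dWs[-1] = dWs[-1] + ts[-1].T @ np.ones((n, 1))
            t_bar = np.broadcast_to(self.weights[-1][:, 0], a_bar.shape).copy()

        for l in range(L - 2, -1, -1):
            z = zs[l]
            sp = gelu_d1(z)
            z_bar = sp * a_bar
            if with_v:
                z_bar = z_bar + gelu_d2(z) * us[l] * t_bar
                u_bar = sp * t_bar
            dWs[l] = acts[l].T @ z_bar
            dbs[l] = z_bar.sum(axis=0)
            if with_v:
                dWs[l] = dWs[l] + ts[l].T @ u_bar
            if l > 0:
                a_bar = z_bar @ self.weights[l].T
                if with_v:
                    t_bar = u_bar @ self.weights[l].T
        return dWs, dbs


@dataclass(frozen=True)
class SAETable:
    """Element-wise energy offsets (Hartree per atom), the linear centering."""

    offsets: dict[str, float]

    def vector(self, element_order: Sequence[str]) -> np.ndarray:
        return np.array([self.offsets[e] for e in element_order])

    def molecule_energy(self, molecule: Molecule) -> float:
        try:
            return float(sum(self.offsets[e] for e in molecule.elements))
        except KeyError as exc:
            raise MoleculeError(f"element {exc.args[0]} missing from SAE table")

    @classmethod
    def zeros(cls, elements: Sequence[str]) -> "SAETable":
        return cls({e: 0.0 for e in elements})


def fit_sae(records: Sequence[LabeledRecord], element_order: Sequence[str]) -> SAETable:
    """Least-squares element offsets from reference energies vs composition."""
    if len(records) < len(element_order):
        raise MoleculeError(
            f"need at least {len(element_order)} records to fit {len(element_order)} offsets"
        )
    comp = np.array([composition_vector(r.molecule, element_order) for r in records], dtype=float)
    energies = np.array([r.energy for r in records])
    rank = np.linalg.matrix_rank(comp)
    if rank < len(element_order):
        _, s, vt = np.linalg.svd(comp)
        null = vt[rank:]
        bad = [element_order[i] for i in range(len(element_order))
               if np.any(np.abs(null[:, i]) > 1e-8)]
        raise MoleculeError(
            f"composition matrix is rank-deficient: offsets for elements {bad} "
            "cannot be resolved from this dataset"
        )
    sol, *_ = np.linalg.lstsq(comp, energies, rcond=None)
    return SAETable({e: float(v) for e, v in zip(element_order, sol)})


class ModelEnsemble:
    """Ensemble of per-element networks sharing an SAE table and AEV params."""

    def __init__(
        self,
        members: list[dict[str, ElementNetwork]],
        sae: SAETable,
        aev_params: AEVParams,
        meta: dict | None = None,
    ):
        if not members:
            raise ValueError("ensemble needs at least one member")
        arch = {e: net.layer_sizes for e, net in members[0].items()}
        for m in members[1:]:
            if {e: net.layer_sizes for e, net in m.items()} != arch:
                raise ValueError("all ensemble members must share one architecture")
        self.members = members
        self.sae = sae
        self.aev_params = aev_params
        self.meta = meta or {}

    @classmethod
    def create(
        cls,
        aev_params: AEVParams,
        n_members: int = 8,
        hidden: Sequence[int] = DEFAULT_HIDDEN,
        seed: int = 0,
        sae: SAETable | None = None,
    ) -> "ModelEnsemble":
        sizes = (aev_params.feature_length, *hidden, 1)
        members = []
        for m in range(n_members):
            rng = np.random.default_rng(np.random.SeedSequence([seed, m]))
            members.append({e: ElementNetwork(e, sizes, rng) for e in aev_params.elements})
        return cls(members, sae or SAETable.zeros(aev_params.elements), aev_params,
                   meta={"stage": "init", "seed": seed})

    @property
    def n_members(self) -> int:
        return len(self.members)

    def copy(self) -> "ModelEnsemble":
        return ModelEnsemble(
            [{e: net.copy() for e, net in m.items()} for m in self.members],
            SAETable(dict(self.sae.offsets)), self.aev_params, dict(self.meta),
        )

    # ---- evaluation -----------------------------------------------------

    def _element_batches(self, elements: Sequence[str], feats: np.ndarray):
        batches = {}
        for e in set(elements):
            idx = np.array([i for i, s in enumerate(elements) if s == e])
            batches[e] = (idx, feats[idx])
        return batches

    def member_energies(self, molecule: Molecule, desc: AEVDescriptor | None = None) -> np.ndarray:
        if desc is None:
            desc = compute_aev(molecule, self.aev_params)
        sae_e = self.sae.molecule_energy(molecule)
        batches = self._element_batches(desc.elements, desc.features)
        out = np.empty(self.n_members)
        for m, nets in enumerate(self.members):
            total = sae_e
            for e, (idx, x) in batches.items():
                vals, _ = nets[e].forward(x)
                total += vals.sum()
            out[m] = total
        return out

    def energy(self, molecule: Molecule, desc: AEVDescriptor | None = None):
        """Ensemble-mean neural energy; returns (E, per-member array, spread)."""
        vals = self.member_energies(molecule, desc)
        return float(vals.mean()), vals, float(vals.std())

    def forces(self, molecule: Molecule):
        """Ensemble-mean forces -dE/dR (Hartree/Angstrom)."""
        desc, jac = compute_aev(molecule, self.aev_params, jacobian=True)
        batches = self._element_batches(desc.elements, desc.features)
        n = molecule.n_atoms
        grad = np.zeros((n, desc.features.shape[1]))
        for nets in self.members:
            for e, (idx, x) in batches.items():
                _, cache = nets[e].forward(x)
                grad[idx] += nets[e].input_grad(cache)
        grad /= self.n_members
        # dE/dR[a,k] = sum_{i,f} grad[i,f] * J[i,f,a,k]
        return -np.einsum("if,ifak->ak", grad, jac)


def nn_energy(ensemble: ModelEnsemble, molecule: Molecule):
    """Module-level convenience: (ensemble mean E_NN, member energies, spread)."""
    return ensemble.energy(molecule)


def nn_forces(ensemble: ModelEnsemble, molecule: Molecule) -> np.ndarray:
    return ensemble.forces(molecule)


# ---- checkpointing ------------------------------------------------------


def save_ensemble(path, ensemble: ModelEnsemble) -> None:
    """Write an ensemble checkpoint (single .npz archive, bit-exact reload)."""
    arrays = {}
    for m, nets in enumerate(ensemble.members):
        for e, net in nets.items():
            for l, (w, b) in enumerate(zip(net.weights, net.biases)):
                arrays[f"m{m}.{e}.W{l}"] = w
                arrays[f"m{m}.{e}.b{l}"] = b
    meta = {
        "n_members": ensemble.n_members,
        "aev_params": ensemble.aev_params.to_dict(),
        "sae": ensemble.sae.offsets,
        "meta": ensemble.meta,
        "layer_sizes": {e: list(net.layer_sizes) for e, net in ensemble.members[0].items()},
    }
    arrays["metadata_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_ensemble(path) -> ModelEnsemble:
    with np.load(path) as data:
        meta = json.loads(bytes(data["metadata_json"]))
        members = []
        for m in range(meta["n_members"]):
            nets = {}
            for e, sizes in meta["layer_sizes"].items():
                net = ElementNetwork.__new__(ElementNetwork)
                net.element = e
                net.layer_sizes = tuple(sizes)
                net.weights, net.biases = [], []
                for l in range(len(sizes) - 1):
                    net.weights.append(data[f"m{m}.{e}.W{l}"].copy())
                    net.biases.append(data[f"m{m}.{e}.b{l}"].copy())
                nets[e] = net
            members.append(nets)
    return ModelEnsemble(
        members,
        SAETable(dict(meta["sae"])),
        AEVParams.from_dict(meta["aev_params"]),
        meta["meta"],
    )
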