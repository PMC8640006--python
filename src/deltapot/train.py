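"""Two-stage training: delta-learning then transfer learning.

Stage 1 fits the per-element networks to centered differences between a
mid-level reference and the baseline (energies and, when present, forces)
with the geometric-mean loss L = sqrt(L_E * L_F).  Stage 2 re-fits the
ensemble to a higher-level reference using energies only, with the first
and third hidden layers frozen (counting hidden layers 1-based from the
input side).

Loss conventions: L_E is the mean over records of the squared per-record
energy error scaled by 1/sqrt(N_atoms); L_F is the plain mean squared error
over force components.  Optimization is Adam with factor-0.5 learning-rate
reduction on validation plateau; everything is deterministic for a given
seed on a fixed thread configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aev import AEVParams, compute_aev
from .chem import LabeledRecord, MoleculeError
from .nnpot import (DEFAULT_HIDDEN, ElementNetwork, ModelEnsemble, SAETable,
                    fit_sae)

OUTLIER_THRESHOLD = 0.01  # Hartree; |centered label| above this is flagged


@dataclass(frozen=True)
class LossTerms:
    """Energy and force loss terms and their combination."""

    energy: float
    force: float | None = None

    @property
    def total(self) -> float:
        if self.force is None:
            return self.energy
        return float(np.sqrt(self.energy * self.force))


def compute_loss(
    pred_energies: np.ndarray,
    ref_energies: np.ndarray,
    n_atoms: np.ndarray,
    pred_forces: Sequence[np.ndarray] | None = None,
    ref_forces: Sequence[np.ndarray] | None = None,
    with_forces: bool = False,
) -> LossTerms:
    """Geometric-mean loss; energy-only mode ignores any force arrays."""
    pred_energies = np.asarray(pred_energies, dtype=float)
    ref_energies = np.asarray(ref_energies, dtype=float)
    if pred_energies.size == 0:
        raise ValueError("at least one record required")
    l_e = float(np.mean(((pred_energies - ref_energies) / np.sqrt(n_atoms)) ** 2))
    if not with_forces:
        return LossTerms(l_e)
    if ref_forces is None or any(f is None for f in ref_forces):
        raise MoleculeError("force loss requested but reference forces are missing")
    num = sum(float(np.sum((p - r) ** 2)) for p, r in zip(pred_forces, ref_forces))
    den = sum(r.size for r in ref_forces)
    return LossTerms(l_e, num / den)


@dataclass(frozen=True)
class SplitPlan:
    """Nine-way (by default) partition with rotated validation parts.

    One part is held out for testing; each ensemble member validates on a
    distinct remaining part and trains on the other parts.
    """

    parts: tuple[tuple[int, ...], ...]
    test_part: int
    member_val_parts: tuple[int, ...]
    seed: int

    def train_indices(self, member: int) -> np.ndarray:
        val = self.member_val_parts[member]
        out = []
        for p, idx in enumerate(self.parts):
            if p not in (self.test_part, val):
                out.extend(idx)
        return np.array(sorted(out))

    def val_indices(self, member: int) -> np.ndarray:
        return np.array(sorted(self.parts[self.member_val_parts[member]]))

    def test_indices(self) -> np.ndarray:
        return np.array(sorted(self.parts[self.test_part]))


def make_split_plan(
    n_records: int, n_parts: int = 9, n_members: int = 8, seed: int = 0,
    test_part: int = 0,
) -> SplitPlan:
    if n_records < n_parts:
        raise ValueError(f"cannot split {n_records} records into {n_parts} parts")
    if n_members > n_parts - 1:
        raise ValueError(
            f"{n_members} members need {n_members} distinct validation parts; "
            f"only {n_parts - 1} non-test parts available"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_records)
    parts = tuple(tuple(int(i) for i in chunk) for chunk in np.array_split(perm, n_parts))
    val_parts = tuple(p for p in range(n_parts) if p != test_part)[:n_members]
    return SplitPlan(parts, test_part, val_parts, seed)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training stage."""

    max_epochs: int = 1000
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_patience: int = 25           # epochs without val improvement before halving
    min_lr: float = 1e-5
    stage: str = "delta"            # "delta" | "transfer"
    frozen_hidden_layers: tuple[int, ...] = (1, 3)  # 1-based over hidden layers
    transfer_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_members: int = 8
    n_parts: int = 9
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    seed: int = 0
    outlier_threshold: float = OUTLIER_THRESHOLD

    def __post_init__(self) -> None:
        if abs(sum(self.transfer_fractions) - 1.0) > 1e-9:
            raise ValueError("transfer fractions must sum to 1")


def flag_outliers(centered: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of records whose centered label magnitude exceeds threshold.

    Flagged for review, never silently dropped.
    """
    return np.nonzero(np.abs(centered) > threshold)[0]


# ---- dataset precomputation --------------------------------------------


class _PreparedDataset:
    """AEVs (and Jacobians when training forces) cached once per record."""

    def __init__(self, records, baseline, aev_params: AEVParams, sae: SAETable,
                 with_forces: bool, extra_providers=()):
        self.records = records
        self.aev_params = aev_params
        self.with_forces = with_forces
        self.n_atoms = np.array([r.molecule.n_atoms for r in records])
        self.targets = np.empty(len(records))
        self.force_targets: list[np.ndarray | None] = []
        self.feats: list[np.ndarray] = []
        self.jacs: list[np.ndarray | None] = []
        self.element_rows: list[dict[str, np.ndarray]] = []
        for i, rec in enumerate(records):
            mol = rec.molecule
            base_e = baseline.energy(mol) if baseline is not None else 0.0
            for prov in extra_providers:
                base_e += prov.energy(mol)
            self.targets[i] = rec.energy - base_e - sae.molecule_energy(mol)
            if with_forces and rec.forces is not None:
                base_f = baseline.forces(mol) if baseline is not None else 0.0
                for prov in extra_providers:
                    base_f = base_f + prov.forces(mol)
                self.force_targets.append(rec.forces - base_f)
            else:
                self.force_targets.append(None)
            if with_forces:
                desc, jac = compute_aev(mol, aev_params, jacobian=True)
            else:
                desc, jac = compute_aev(mol, aev_params), None
            self.feats.append(desc.features)
            self.jacs.append(jac)
            rows = {}
            for e in set(mol.elements):
                rows[e] = np.array([a for a, s in enumerate(mol.elements) if s == e])
            self.element_rows.append(rows)

    def __len__(self) -> int:
        return len(self.records)


# ---- Adam over an element-network dict ---------------------------------


class _AdamState:
    def __init__(self, nets: dict[str, ElementNetwork]):
        self.m = {e: [np.zeros_like(w) for w in _params(n)] for e, n in nets.items()}
        self.v = {e: [np.zeros_like(w) for w in _params(n)] for e, n in nets.items()}
        self.t = 0

    def step(self, nets, grads, lr, frozen_param_idx, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for e, net in nets.items():
            params = _params(net)
            for k, (p, g) in enumerate(zip(params, grads[e])):
                if k in frozen_param_idx:
                    continue
                m = self.m[e][k] = b1 * self.m[e][k] + (1 - b1) * g
                v = self.v[e][k] = b2 * self.v[e][k] + (1 - b2) * g * g
                p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


def _params(net: ElementNetwork) -> list[np.ndarray]:
    out = []
    for w, b in zip(net.weights, net.biases):
        out.append(w)
        out.append(b)
    return out


def frozen_param_indices(net: ElementNetwork, frozen_hidden: Sequence[int]) -> set[int]:
    """Flat parameter indices (W0,b0,W1,b1,...) of frozen hidden layers.

    Hidden layer h (1-based) is produced by weight matrix h-1.
    """
    idx = set()
    for h in frozen_hidden:
        if not (1 <= h <= net.n_hidden):
            raise ValueError(
                f"cannot freeze hidden layer {h}: network has {net.n_hidden} hidden layers"
            )
        idx.add(2 * (h - 1))
        idx.add(2 * (h - 1) + 1)
    return idx


# ---- single-member training loop ---------------------------------------


def _gather_batch(data: _PreparedDataset, indices):
    """Concatenate AEV rows of a set of records, grouped by element.

    Returns {element: (X, record_pos, atom_rows)} where ``record_pos`` maps
    each concatenated row to its position within ``indices`` and
    ``atom_rows`` to its atom index inside the record.
    """
    groups: dict[str, list] = {}
    for pos, i in enumerate(indices):
        for e, rows in data.element_rows[i].items():
            groups.setdefault(e, []).append((pos, i, rows))
    out = {}
    for e, items in groups.items():
        x = np.concatenate([data.feats[i][rows] for _, i, rows in items])
        pos = np.concatenate([np.full(len(rows), p) for p, _, rows in items])
        arows = np.concatenate([rows for _, _, rows in items])
        out[e] = (x, pos, arows)
    return out


def _member_predictions(nets, data: _PreparedDataset, indices, forces=False):
    indices = np.asarray(indices)
    e_pred = np.zeros(len(indices))
    groups = _gather_batch(data, indices)
    grads = {pos: np.zeros_like(data.feats[i]) for pos, i in enumerate(indices)} if forces else None
    for e, (x, pos, arows) in groups.items():
        vals, cache = nets[e].forward(x)
        np.add.at(e_pred, pos, vals)
        if forces:
            g = nets[e].input_grad(cache)
            for row in range(len(pos)):
                grads[pos[row]][arows[row]] = g[row]
    if not forces:
        return e_pred
    f_pred = [
        -np.einsum("if,ifak->ak", grads[p], data.jacs[i])
        for p, i in enumerate(indices)
    ]
    return e_pred, f_pred


def _member_loss(nets, data, indices, with_forces):
    if with_forces:
        e_pred, f_pred = _member_predictions(nets, data, indices, forces=True)
        return compute_loss(
            e_pred, data.targets[indices], data.n_atoms[indices],
            f_pred, [data.force_targets[i] for i in indices], with_forces=True,
        )
    e_pred = _member_predictions(nets, data, indices)
    return compute_loss(e_pred, data.targets[indices], data.n_atoms[indices])


def _train_member(
    nets: dict[str, ElementNetwork],
    data: _PreparedDataset,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainConfig,
    with_forces: bool,
    rng: np.random.Generator,
    frozen_hidden: Sequence[int] = (),
):
    """Adam training of one member; returns per-epoch history."""
    any_net = next(iter(nets.values()))
    frozen_idx = frozen_param_indices(any_net, frozen_hidden) if frozen_hidden else set()
    adam = _AdamState(nets)
    lr = config.learning_rate
    best_val = np.inf
    best_snapshot = None
    stale = 0
    history = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            grads = _batch_gradients(nets, data, batch, with_forces)
            adam.step(nets, grads, lr, frozen_idx)
        val = _member_loss(nets, data, val_idx, with_forces)
        train = _member_loss(nets, data, train_idx, with_forces)
        history.append({
            "epoch": epoch, "lr": lr,
            "train_E": train.energy, "train_F": train.force, "train": train.total,
            "val_E": val.energy, "val_F": val.force, "val": val.total,
        })
        if val.total < best_val - 1e-14:
            best_val = val.total
            best_snapshot = {e: ([w.copy() for w in n.weights],
                                 [b.copy() for b in n.biases]) for e, n in nets.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.lr_patience:
                lr *= 0.5
                stale = 0
                if lr < config.min_lr:
                    break
    if best_snapshot is not None:
        for e, (ws, bs) in best_snapshot.items():
            nets[e].weights = ws
            nets[e].biases = bs
    return history


def _batch_gradients(nets, data: _PreparedDataset, batch, with_forces):
    """Gradients of the (geometric-mean) batch loss w.r.t. all parameters."""
    batch = np.asarray(batch)
    n_batch = len(batch)
    groups = _gather_batch(data, batch)

    caches = {}
    e_pred = np.zeros(n_batch)
    g_rows = {}  # element -> per-row input gradients
    for e, (x, pos, arows) in groups.items():
        vals, cache = nets[e].forward(x)
        caches[e] = cache
        np.add.at(e_pred, pos, vals)
        if with_forces:
            g_rows[e] = nets[e].input_grad(cache)

    n_at = data.n_atoms[batch]
    e_err = e_pred - data.targets[batch]
    l_e = float(np.mean((e_err / np.sqrt(n_at)) ** 2))
    dl_e = 2.0 * e_err / n_at / n_batch  # d L_E / d E_pred, per record

    v_rec = None
    if with_forces:
        # assemble per-record input-gradient matrices, then force residuals
        g_rec = [np.zeros_like(data.feats[i]) for i in batch]
        for e, (x, pos, arows) in groups.items():
            g = g_rows[e]
            for row in range(len(pos)):
                g_rec[pos[row]][arows[row]] = g[row]
        n_comp = sum(data.force_targets[i].size for i in batch)
        l_f_num = 0.0
        v_rec = []
        for bi, i in enumerate(batch):
            f_pred = -np.einsum("if,ifak->ak", g_rec[bi], data.jacs[i])
            resid = f_pred - data.force_targets[i]
            l_f_num += float(np.sum(resid**2))
            # dL_F/dG[i,:] = -2/M * sum_{a,k} resid[a,k] J[i,:,a,k]
            v_rec.append(-2.0 / n_comp * np.einsum("ak,ifak->if", resid, data.jacs[i]))
        l_f = l_f_num / n_comp
        # L = sqrt(L_E L_F): chain coefficients for each term
        a_e = 0.5 * np.sqrt(max(l_f, 1e-300) / max(l_e, 1e-300))
        a_f = 0.5 * np.sqrt(max(l_e, 1e-300) / max(l_f, 1e-300))
    else:
        a_e, a_f = 1.0, 0.0

    grads = {e: [np.zeros_like(p) for p in _params(n)] for e, n in nets.items()}
    for e, (x, pos, arows) in groups.items():
        out_bar = a_e * dl_e[pos]
        v = None
        if with_forces:
            v = a_f * np.stack([v_rec[pos[row]][arows[row]] for row in range(len(pos))])
        dws, dbs = nets[e].param_grads(caches[e], out_bar, v)
        for k in range(len(dws)):
            grads[e][2 * k] += dws[k]
            grads[e][2 * k + 1] += dbs[k]
    return grads


# ---- stage drivers ------------------------------------------------------


def train_delta_stage(
    baseline,
    records: Sequence[LabeledRecord],
    config: TrainConfig,
    aev_params: AEVParams | None = None,
    sae: SAETable | None = None,
    split: SplitPlan | None = None,
) -> ModelEnsemble:
    """Stage 1: fit an ensemble to centered (reference - baseline) labels.

    The SAE table is fit on the difference labels of the training pool and
    kept fixed thereafter.  Records with |centered label| above the outlier
    threshold are flagged in the returned metadata for review.
    """
    aev_params = aev_params or AEVParams()
    if split is None:
        split = make_split_plan(len(records), config.n_parts, config.n_members,
                                seed=config.seed)
    if sae is None:
        diff = [
            LabeledRecord(r.molecule, r.energy - baseline.energy(r.molecule))
            for r in records
        ]
        sae = fit_sae(diff, aev_params.elements)

    with_forces = all(r.forces is not None for r in records)
    data = _PreparedDataset(records, baseline, aev_params, sae, with_forces)
    outliers = flag_outliers(data.targets, config.outlier_threshold)

    ensemble = ModelEnsemble.create(
        aev_params, n_members=config.n_members, hidden=config.hidden,
        seed=config.seed, sae=sae,
    )
    histories = []
    for m, nets in enumerate(ensemble.members):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + m]))
        hist = _train_member(
            nets, data, split.train_indices(m), split.val_indices(m),
            config, with_forces, rng,
        )
        histories.append(hist)
    ensemble.meta.update({
        "stage": "delta", "seed": config.seed,
        "with_forces": with_forces,
        "history": histories,
        "flagged_outliers": [int(i) for i in outliers],
        "split": {"n_parts": config.n_parts, "test_part": split.test_part},
    })
    return ensemble


def transfer_learn(
    ensemble: ModelEnsemble,
    records: Sequence[LabeledRecord],
    baseline,
    config: TrainConfig,
    extra_providers: Sequence = (),
) -> ModelEnsemble:
    """Stage 2: refit to high-level energies with frozen hidden layers 1, 3.

    ``extra_providers`` (e.g. the dispersion term) are subtracted from the
    reference alongside the baseline, so the networks learn
    E_high - E_baseline - E_extra.  Forces are not used.  The input
    ensemble is left untouched; a new ensemble with stage "transferred" is
    returned, its frozen layers bit-identical to the stage-1 weights.
    """
    out = ensemble.copy()
    data = _PreparedDataset(
        records, baseline, out.aev_params, out.sae, with_forces=False,
        extra_providers=extra_providers,
    )
    n = len(records)
    f_train, f_val, _ = config.transfer_fractions
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    perm = rng.permutation(n)
    n_train = int(round(f_train * n))
    n_val = int(round(f_val * n))
    train_idx = perm[:n_train]
    val_idx = perm[n_train:n_train + n_val]
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("transfer split leaves an empty train or validation set")

    histories = []
    for m, nets in enumerate(out.members):
        mrng = np.random.default_rng(np.random.SeedSequence([config.seed, 2000 + m]))
        hist = _train_member(
            nets, data, train_idx, val_idx, config, with_forces=False,
            rng=mrng, frozen_hidden=config.frozen_hidden_layers,
        )
        histories.append(hist)
    out.meta = dict(out.meta)
    out.meta.update({
        "stage": "transferred", "transfer_seed": config.seed,
        "transfer_history": histories,
        "transfer_split_sizes": [len(train_idx), len(val_idx),
                                 n - len(train_idx) - len(val_idx)],
    })
    return out
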