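"""Molecular data model, unit conventions and XYZ / extended-XYZ I/O.

Internal units are Hartree and Angstrom everywhere; kcal/mol appears only at
reporting boundaries.  The extended-XYZ dialect used throughout the package
stores per-frame scalars as ``key=value`` pairs on the comment line
(``energy`` in Hartree, ``level`` as a free tag) and, when forces are
present, three extra columns per atom row (Hartree/Angstrom).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

# conversion constants (CODATA-derived, fixed here for reproducibility)
HARTREE_TO_KCALMOL = 627.5094740631
HARTREE_TO_EV = 27.211386245988
BOHR_TO_ANGSTROM = 0.529177210903

#: standard atomic weights (amu) and single-bond covalent radii (Angstrom)
ATOMIC_MASSES = {
    "H": 1.00782503207, "C": 12.0, "N": 14.0030740048, "O": 15.9949146196,
    "F": 18.99840322, "S": 31.97207100, "Cl": 34.96885268,
}
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "S": 1.05, "Cl": 1.02,
}

DEFAULT_ELEMENTS = ("H", "C", "N", "O")


class MoleculeError(ValueError):
    """Raised for malformed molecular data or files."""


@dataclass(frozen=True)
class Molecule:
    """Element symbols plus Cartesian coordinates in Angstrom.

    ``charge`` is carried as metadata only: the neural correction is
    charge-blind by construction (identical geometry, identical correction).
    """

    elements: tuple[str, ...]
    coordinates: np.ndarray
    charge: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise MoleculeError(f"coordinates must be N x 3, got {coords.shape}")
        if len(self.elements) != coords.shape[0]:
            raise MoleculeError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise MoleculeError("molecule must contain at least one atom")
        if not np.all(np.isfinite(coords)):
            raise MoleculeError("coordinates must be finite")
        for sym in self.elements:
            if sym not in ATOMIC_MASSES:
                raise MoleculeError(f"unknown element symbol {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    def with_coordinates(self, coords: np.ndarray) -> "Molecule":
        return replace(self, coordinates=np.asarray(coords, dtype=float))

    def distance_matrix(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt(np.sum(d * d, axis=-1))


@dataclass(frozen=True)
class LabeledRecord:
    """A molecule with a reference energy (Hartree) and optional forces."""

    molecule: Molecule
    energy: float
    forces: np.ndarray | None = None
    level_tag: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise MoleculeError("reference energy must be finite")
        if self.forces is not None:
            forces = np.asarray(self.forces, dtype=float)
            object.__setattr__(self, "forces", forces)
            if forces.shape != self.molecule.coordinates.shape:
                raise MoleculeError(
                    f"forces shape {forces.shape} does not match coordinates "
                    f"{self.molecule.coordinates.shape}"
                )


def normalize_symbol(sym: str) -> str:
    return sym[:1].upper() + sym[1:].lower()


def composition_vector(molecule: Molecule, element_order: Sequence[str]) -> np.ndarray:
    """Integer atom counts of ``molecule`` in the order of ``element_order``."""
    index = {e: i for i, e in enumerate(element_order)}
    counts = np.zeros(len(element_order), dtype=int)
    for sym in molecule.elements:
        if sym not in index:
            raise MoleculeError(f"unsupported element {sym} (order {list(element_order)})")
        counts[index[sym]] += 1
    return counts


def _parse_comment_fields(comment: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v.strip('"')
    return fields


def _format_comment(fields: dict[str, object]) -> str:
    return " ".join(f"{k}={v}" for k, v in fields.items())


def read_xyz(source: str | os.PathLike | io.TextIOBase) -> list[Molecule]:
    """Parse a (multi-frame) XYZ or extended-XYZ file into molecules.

    Accepts a path, raw text containing newlines, or an open text stream.
    """
    return [mol for mol, _, _ in _read_frames(source)]


def read_labeled_xyz(source: str | os.PathLike | io.TextIOBase) -> list[LabeledRecord]:
    """Parse extended XYZ into labeled records (requires ``energy=`` per frame)."""
    records = []
    for mol, energy, forces in _read_frames(source):
        if energy is None:
            raise MoleculeError(
                f"frame {len(records) + 1}: no energy= field on comment line"
            )
        tag = _parse_comment_fields(mol.comment).get("level", "")
        records.append(LabeledRecord(mol, energy, forces, level_tag=tag))
    return records


def _open_source(source):
    if isinstance(source, io.TextIOBase):
        return source.read().splitlines()
    text = str(source)
    if "\n" in text:
        return text.splitlines()
    with open(text) as fh:
        return fh.read().splitlines()


def _read_frames(source):
    lines = _open_source(source)
    frames = []
    i, frame_no = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise MoleculeError(
                f"frame {frame_no}, line {i + 1}: bad atom-count line {lines[i]!r}"
            ) from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        rows = lines[i + 2 : i + 2 + natoms]
        if len(rows) < natoms:
            raise MoleculeError(
                f"frame {frame_no}: count line says {natoms} atoms but only "
                f"{len(rows)} atom rows follow"
            )
        elements, coords, forces = [], [], []
        has_forces = False
        for j, row in enumerate(rows):
            parts = row.split()
            if len(parts) not in (4, 7):
                raise MoleculeError(
                    f"frame {frame_no}, line {i + 3 + j}: expected 'El x y z' "
                    f"(optionally fx fy fz), got {row!r}"
                )
            sym = normalize_symbol(parts[0])
            if sym not in ATOMIC_MASSES:
                raise MoleculeError(
                    f"frame {frame_no}, line {i + 3 + j}: unknown element {parts[0]!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise MoleculeError(
                    f"frame {frame_no}, line {i + 3 + j}: coordinate parse failure in {row!r}"
                ) from exc
            elements.append(sym)
            coords.append(xyz)
            if len(parts) == 7:
                has_forces = True
                forces.append([float(p) for p in parts[4:7]])
        meta = _parse_comment_fields(comment)
        charge = int(meta.get("charge", 0))
        mol = Molecule(tuple(elements), np.array(coords), charge=charge, comment=comment)
        energy = float(meta["energy"]) if "energy" in meta else None
        frames.append((mol, energy, np.array(forces) if has_forces else None))
        i += 2 + natoms
    return frames


def write_xyz(
    destination: str | os.PathLike | io.TextIOBase,
    molecules: Molecule | Iterable[Molecule],
) -> None:
    """Write one or more molecules as multi-frame XYZ (15-digit precision)."""
    if isinstance(molecules, Molecule):
        molecules = [molecules]
    text = "".join(_format_frame(m, None, None) for m in molecules)
    _write_text(destination, text)


def write_labeled_xyz(
    destination: str | os.PathLike | io.TextIOBase,
    records: Iterable[LabeledRecord],
) -> None:
    """Write labeled records as extended XYZ with energy/level comment fields."""
    text = "".join(_format_frame(r.molecule, r.energy, r.forces, r.level_tag) for r in records)
    _write_text(destination, text)


def _write_text(destination, text: str) -> None:
    if isinstance(destination, io.TextIOBase):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def _format_frame(mol: Molecule, energy, forces, level_tag: str = "") -> str:
    fields: dict[str, object] = {}
    if energy is not None:
        fields["energy"] = f"{energy:.12f}"
    if mol.charge:
        fields["charge"] = mol.charge
    if level_tag:
        fields["level"] = level_tag
    comment = _format_comment(fields) if fields else mol.comment.replace("\n", " ")
    out = [f"{mol.n_atoms}", comment]
    for a in range(mol.n_atoms):
        row = f"{mol.elements[a]:<2s} " + " ".join(
            f"{c: .12f}" for c in mol.coordinates[a]
        )
        if forces is not None:
            row += " " + " ".join(f"{c: .12f}" for c in forces[a])
        out.append(row)
    return "\n".join(out) + "\n"
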