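"""Molecule ingestion: SMILES standardization, length filtering and graph featurization.

Input molecules arrive as SMILES strings (``.smi`` files or a CSV column).
Standardization strips salt/solvent fragments by keeping the largest connected
component, canonicalizes the survivor, and filters on canonical-SMILES length
(8--140 characters).  Accepted molecules are turned into :class:`MolecularGraph`
objects: a binary adjacency matrix, its self-loop symmetric normalization
``D^{-1/2}(A + I)D^{-1/2}``, and a 54-column one-hot atom feature matrix
(38 atom types incl. an unknown slot, 6 degree bins, 5 formal-charge bins,
4 chirality states, 1 aromaticity flag).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.rdchem import ChiralType

logger = logging.getLogger("fpbench.standardize")

MIN_SMILES_LEN = 8
MAX_SMILES_LEN = 140

#: 37 named element symbols routed to dedicated one-hot slots; anything else
#: falls into the trailing "unknown" slot.  Membership only affects routing,
#: never the 54-column layout.
DEFAULT_ATOM_TYPES: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "As", "Te", "H", "Li", "Na", "K", "Mg", "Ca",
    "Al", "Zn", "Fe", "Cu", "Mn", "Co", "Ni", "Cr", "Mo", "Sn",
    "Ag", "Au", "Pt", "Hg", "Pb", "Bi", "Gd",
)

DEGREE_BINS: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
CHARGE_BINS: tuple[int, ...] = (-2, -1, 0, 1, 2)
CHIRALITY_ORDER: tuple[ChiralType, ...] = (
    ChiralType.CHI_UNSPECIFIED,
    ChiralType.CHI_TETRAHEDRAL_CW,
    ChiralType.CHI_TETRAHEDRAL_CCW,
    # any other chiral tag maps to the fourth ("other") slot
)

N_ATOM_FEATURES = len(DEFAULT_ATOM_TYPES) + 1 + len(DEGREE_BINS) + len(CHARGE_BINS) + 4 + 1
assert N_ATOM_FEATURES == 54


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class MoleculeRecord:
    """A molecule as it moves through standardization and filtering."""

    id: str
    smiles_raw: str
    smiles_std: str | None = None
    accepted: bool = False
    reason: str = ""


@dataclass
class MolecularGraph:
    """Graph view of one molecule: adjacency, its normalization, atom features."""

    node_count: int
    adjacency: np.ndarray
    adjacency_norm: np.ndarray
    node_features: np.ndarray
    smiles: str = ""

    @classmethod
    def from_mol(cls, mol: Chem.Mol, smiles: str = "") -> "MolecularGraph":
        a = build_adjacency(mol)
        return cls(
            node_count=mol.GetNumAtoms(),
            adjacency=a,
            adjacency_norm=normalize_adjacency(a),
            node_features=featurize_atoms(mol),
            smiles=smiles or Chem.MolToSmiles(mol),
        )

    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
        return cls.from_mol(mol, smiles=smiles)


def standardize_smiles(raw: str) -> str:
    """Canonical SMILES of the largest fragment (salt/solvent stripping).

    The largest connected component by heavy-atom count is kept; ties break on
    the lexicographically smallest canonical SMILES.  Deterministic.
    """
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {raw!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return Chem.MolToSmiles(mol)
    keyed = [(f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)) for f in frags]
    # max heavy atoms; ties -> lexicographically smallest canonical SMILES
    best = min(keyed, key=lambda t: (-t[0], t[1]))
    return best[1]


def make_record(mol_id: str, raw: str) -> MoleculeRecord:
    """Standardize one raw SMILES into a :class:`MoleculeRecord` (never raises)."""
    rec = MoleculeRecord(id=mol_id, smiles_raw=raw)
    try:
        rec.smiles_std = standardize_smiles(raw)
        rec.accepted = True
    except SmilesParseError as exc:
        rec.accepted = False
        rec.reason = str(exc)
    return rec


def filter_by_length(
    records: Iterable[MoleculeRecord],
    min_len: int = MIN_SMILES_LEN,
    max_len: int = MAX_SMILES_LEN,
) -> list[MoleculeRecord]:
    """Keep records whose standardized SMILES length is within [min_len, max_len].

    Rejected records get ``accepted=False`` and a reason; the accepted subset
    is returned.  Idempotent after standardization.
    """
    kept: list[MoleculeRecord] = []
    for rec in records:
        if not rec.accepted or rec.smiles_std is None:
            continue
        n = len(rec.smiles_std)
        if n < min_len:
            rec.accepted = False
            rec.reason = f"standardized SMILES length {n} < {min_len}"
        elif n > max_len:
            rec.accepted = False
            rec.reason = f"standardized SMILES length {n} > {max_len}"
        else:
            kept.append(rec)
    return kept


def standardize_and_filter(
    items: Sequence[tuple[str, str]],
    min_len: int = MIN_SMILES_LEN,
    max_len: int = MAX_SMILES_LEN,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Run the full ingestion on ``(id, smiles)`` pairs; return (accepted, all)."""
    records = [make_record(i, s) for i, s in items]
    accepted = filter_by_length(records, min_len=min_len, max_len=max_len)
    return accepted, records


def _onehot_index(value: int, bins: Sequence[int], what: str, atom_idx: int) -> int:
    if value in bins:
        return bins.index(value)
    nearest = min(range(len(bins)), key=lambda i: abs(bins[i] - value))
    logger.warning(
        "atom %d: %s %d outside bins %s, mapped to nearest bin %d",
        atom_idx, what, value, bins, bins[nearest],
    )
    return nearest


def featurize_atoms(
    mol: Chem.Mol, atom_types: Sequence[str] = DEFAULT_ATOM_TYPES
) -> np.ndarray:
    """Per-atom one-hot feature matrix, |V| x 54.

    Blocks: atom type (len(atom_types) named + 1 unknown), degree (6 bins,
    0--5), formal charge (5 bins, -2..+2), chirality (unspecified/CW/CCW/other),
    and a single aromaticity flag.  Row sums are 4 for non-aromatic atoms and
    5 for aromatic ones.
    """
    n_types = len(atom_types) + 1
    n_cols = n_types + len(DEGREE_BINS) + len(CHARGE_BINS) + 4 + 1
    out = np.zeros((mol.GetNumAtoms(), n_cols))
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        t = atom_types.index(sym) if sym in atom_types else n_types - 1
        out[i, t] = 1.0
        off = n_types
        out[i, off + _onehot_index(atom.GetDegree(), DEGREE_BINS, "degree", i)] = 1.0
        off += len(DEGREE_BINS)
        out[i, off + _onehot_index(atom.GetFormalCharge(), CHARGE_BINS, "charge", i)] = 1.0
        off += len(CHARGE_BINS)
        tag = atom.GetChiralTag()
        chi = CHIRALITY_ORDER.index(tag) if tag in CHIRALITY_ORDER else 3
        out[i, off + chi] = 1.0
        off += 4
        if atom.GetIsAromatic():
            out[i, off] = 1.0
    return out


def build_adjacency(mol: Chem.Mol) -> np.ndarray:
    """Binary symmetric adjacency with zero diagonal; bond order ignored."""
    n = mol.GetNumAtoms()
    a = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        a[i, j] = a[j, i] = 1.0
    return a


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Self-loop symmetric normalization ``D^{-1/2}(A + I)D^{-1/2}``.

    ``D`` is the diagonal degree matrix of ``A + I``; isolated atoms get
    degree 1 from the self-loop, so the result is always finite, symmetric,
    with entries in (0, 1] wherever ``A + I`` is nonzero.
    """
    a_self = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_self.sum(axis=1))
    return a_self * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# I/O helpers

def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file: one record per line, ``SMILES<tab>id`` (id optional)."""
    items: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
        items.append((mol_id, smiles))
    return items


def read_smiles_csv(path: str | Path, smiles_col: str = "smiles", id_col: str = "id") -> list[tuple[str, str]]:
    """Read ``(id, smiles)`` pairs from a CSV with a smiles column."""
    items: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            mol_id = row.get(id_col) or f"mol{i}"
            items.append((mol_id, row[smiles_col]))
    return items


def write_records_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write accepted/rejected records with reasons."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles_raw", "smiles_std", "accepted", "reason"])
        for r in records:
            w.writerow([r.id, r.smiles_raw, r.smiles_std or "", int(r.accepted), r.reason])


def save_graphs(graphs: Sequence[MolecularGraph], path: str | Path) -> None:
    """Serialize graphs as a compressed matrix bundle (npz)."""
    arrays: dict[str, np.ndarray] = {"n_graphs": np.array([len(graphs)])}
    for i, g in enumerate(graphs):
        arrays[f"a_{i}"] = g.adjacency
        arrays[f"x_{i}"] = g.node_features
        arrays[f"s_{i}"] = np.frombuffer(g.smiles.encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_graphs(path: str | Path) -> list[MolecularGraph]:
    with np.load(path) as data:
        n = int(data["n_graphs"][0])
        out = []
        for i in range(n):
            a = data[f"a_{i}"]
            out.append(
                MolecularGraph(
                    node_count=a.shape[0],
                    adjacency=a,
                    adjacency_norm=normalize_adjacency(a),
                    node_features=data[f"x_{i}"],
                    smiles=bytes(data[f"s_{i}"]).decode(),
                )
            )
    return out
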