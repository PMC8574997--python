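"""Rule-based binary fingerprints and the shared fingerprint-matrix container.

Morgan (2D circular, 300 or 1024 bits, radius 2 by default) and topological
path-based (1024 bits, paths 1--7) fingerprints are generated with RDKit.
A 3D circular fingerprint slot exists as an optional adapter: the backend is
not shipped, so calling it without registering one raises a capability error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .standardize import SmilesParseError

#: bit lengths produced by the shipped generators (rule-based + learned)
ALLOWED_BITS = frozenset({16, 64, 256, 300, 1024})
MORGAN_BITS = frozenset({300, 1024})
DEFAULT_MORGAN_RADIUS = 2


class ConfigError(ValueError):
    """Invalid fingerprint configuration (e.g. unsupported bit length)."""


class CapabilityError(RuntimeError):
    """An optional backend (3D fingerprints) is not available."""


@dataclass
class FingerprintMatrix:
    """m compounds x n bits, binary or continuous, with provenance tags."""

    values: np.ndarray
    data_format: str            # "binary" | "continuous"
    fp_type: str                # "rule" | "data"
    fp_subtype: str             # "circular-2D" | "circular-3D" | "path" | "graph" | "sequence"
    n_bits: int
    compound_ids: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("fingerprint values must be a 2-D matrix")
        m, n = self.values.shape
        if n != self.n_bits:
            raise ConfigError(f"n_bits={self.n_bits} but matrix has {n} columns")
        if len(self.compound_ids) != m:
            raise ConfigError("compound_ids must align with matrix rows")
        if len(set(self.compound_ids)) != m:
            raise ConfigError("compound_ids must be unique")
        if self.data_format == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ConfigError("binary fingerprint matrix contains non-{0,1} values")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    def row(self, compound_id: str) -> np.ndarray:
        return self.values[self.compound_ids.index(compound_id)]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id"] + [f"bit{i}" for i in range(self.n_bits)])
            for cid, row in zip(self.compound_ids, self.values):
                w.writerow([cid] + list(row))

    @classmethod
    def from_csv(cls, path: str | Path, **tags) -> "FingerprintMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header, body = rows[0], rows[1:]
        ids = [r[0] for r in body]
        values = np.array([[float(v) for v in r[1:]] for r in body])
        binary = bool(np.isin(values, (0.0, 1.0)).all())
        defaults = dict(
            data_format="binary" if binary else "continuous",
            fp_type="rule", fp_subtype="path", name=Path(path).stem,
        )
        defaults.update(tags)
        return cls(values=values, n_bits=values.shape[1], compound_ids=ids, **defaults)


def _parse(mol: str | Chem.Mol) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise SmilesParseError(f"unparseable SMILES: {mol!r}")
    return parsed


def morgan_fingerprint(
    mol: str | Chem.Mol, n_bits: int = 1024, radius: int = DEFAULT_MORGAN_RADIUS
) -> np.ndarray:
    """Folded binary Morgan (extended-connectivity) fingerprint."""
    if n_bits not in MORGAN_BITS:
        raise ConfigError(f"Morgan n_bits must be one of {sorted(MORGAN_BITS)}, got {n_bits}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.array(gen.GetFingerprint(_parse(mol)), dtype=float)


def topological_fingerprint(
    mol: str | Chem.Mol, n_bits: int = 1024, min_path: int = 1, max_path: int = 7
) -> np.ndarray:
    """Folded binary path-based (topological) fingerprint."""
    if n_bits <= 0:
        raise ConfigError(f"n_bits must be positive, got {n_bits}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        minPath=min_path, maxPath=max_path, fpSize=n_bits
    )
    return np.array(gen.GetFingerprint(_parse(mol)), dtype=float)


#: optional registry for a 3D circular fingerprint backend
_E3FP_BACKEND: Callable[[Chem.Mol, int], np.ndarray] | None = None


def register_e3fp_backend(fn: Callable[[Chem.Mol, int], np.ndarray] | None) -> None:
    global _E3FP_BACKEND
    _E3FP_BACKEND = fn


def e3fp_adapter(mol: str | Chem.Mol, n_bits: int = 1024) -> np.ndarray:
    """3D circular fingerprint via a pluggable backend (not shipped)."""
    if _E3FP_BACKEND is None:
        raise CapabilityError(
            "no 3D fingerprint backend registered; conformer-based fingerprints "
            "require register_e3fp_backend(fn)"
        )
    vec = np.asarray(_E3FP_BACKEND(_parse(mol), n_bits), dtype=float)
    if vec.shape != (n_bits,):
        raise ConfigError(f"3D backend returned shape {vec.shape}, expected ({n_bits},)")
    return vec


_KINDS: dict[str, tuple[Callable[..., np.ndarray], dict, str, str]] = {
    "morgan300": (morgan_fingerprint, {"n_bits": 300}, "circular-2D", "binary"),
    "morgan1024": (morgan_fingerprint, {"n_bits": 1024}, "circular-2D", "binary"),
    "topo1024": (topological_fingerprint, {"n_bits": 1024}, "path", "binary"),
    "e3fp1024": (e3fp_adapter, {"n_bits": 1024}, "circular-3D", "binary"),
}


def fingerprint_molecules(
    items: Sequence[tuple[str, str]], kind: str, **overrides
) -> FingerprintMatrix:
    """Fingerprint ``(id, smiles)`` pairs into a :class:`FingerprintMatrix`.

    ``kind`` is one of morgan300, morgan1024, topo1024, e3fp1024.
    """
    if kind not in _KINDS:
        raise ConfigError(f"unknown fingerprint kind {kind!r}; choose from {sorted(_KINDS)}")
    fn, kwargs, subtype, fmt = _KINDS[kind]
    kwargs = {**kwargs, **overrides}
    ids = [i for i, _ in items]
    values = np.stack([fn(s, **kwargs) for _, s in items])
    return FingerprintMatrix(
        values=values, data_format=fmt, fp_type="rule", fp_subtype=subtype,
        n_bits=values.shape[1], compound_ids=ids, name=kind,
    )
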