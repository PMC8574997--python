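"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`gen_molecules` — valid SMILES assembled from a curated fragment
  grammar (alkyl/aryl/heteroatom/charged/chiral units around one of ten ring
  scaffolds), with a small fraction of too-short and too-long strings so the
  8--140 length filter is exercised, and occasional salt fragments so
  standardization is exercised.
* :func:`gen_screen` — drug-pair x cell-line response tables with a planted
  linear structure->score signal of tunable variance fraction rho, biological
  replicates, and five correlated response scores (CSS-like sensitivity plus
  four synergy-like scores); the generating parameters are returned so
  recovery can be tested.
* :func:`gen_class_labels` — ten structure-correlated classes recovered from
  the scaffold each molecule was built around, emulating level-1 therapeutic
  class assignments.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .rulefp import ConfigError

SCORES = ("css", "bliss", "hsa", "loewe", "zip")

#: ten ring scaffolds; each generated molecule is built around one of them.
#: Written so the last atom is a chain-extendable carbon and matching is
#: mutually exclusive under substructure search.
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",     # benzene
    "c1ccncc1",     # pyridine
    "c1ncncc1",     # pyrimidine
    "c1occc1",      # furan
    "c1sccc1",      # thiophene
    "c1[nH]ccc1",   # pyrrole
    "C1CCCCC1",     # cyclohexane
    "C1CCCC1",      # cyclopentane
    "C1CCNCC1",     # piperidine
    "C1CCOCC1",     # tetrahydropyran
)

# acyclic chain units that concatenate into valid SMILES; rings only come
# from scaffolds so class labels stay scaffold-pure
_CHAIN_UNITS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)", "C(CC)", "CO", "CN", "OC", "NC",
    "C(F)", "C(Cl)", "C(Br)", "C(=O)", "C(=O)O", "C(=O)N", "N(C)", "SC",
    "[C@H](C)", "[C@@H](C)", "[C@H](O)", "[C@@H](F)",
)
_TERMINAL_UNITS: tuple[str, ...] = ("C", "CC", "O", "N", "C(=O)[O-]", "C[N+](C)(C)C", "F", "Cl")
_SALTS: tuple[str, ...] = ("[Na+]", "[Cl-]", "O", "[K+]")
_TINY: tuple[str, ...] = ("CCO", "CCN", "CO", "CC", "C=O")


def gen_molecules(n: int, seed: int = 0) -> list[str]:
    """Generate ``n`` valid, standardizable SMILES strings.

    Scaffolds cycle deterministically so all ten families are populated;
    roughly 2% of outputs are deliberately shorter than 8 characters and 2%
    longer than 140 so the length filter has work to do; 5% carry a salt
    fragment.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for i in range(n):
        roll = rng.random()
        if roll < 0.02:
            smi = _TINY[rng.integers(len(_TINY))]
        elif roll < 0.04:
            smi = "C" + "C(C)C(=O)N" * 15 + "C"  # 152 chars, over the cap
        else:
            scaffold = SCAFFOLDS[i % len(SCAFFOLDS)]
            n_pre = int(rng.integers(1, 4))
            n_suf = int(rng.integers(1, 5))
            # a bracket chiral atom cannot start a molecule (it would be
            # missing a fourth neighbor), so the first unit comes from the
            # bracket-free subset
            starters = [u for u in _CHAIN_UNITS if "[" not in u]
            pre = starters[rng.integers(len(starters))] + "".join(
                _CHAIN_UNITS[j] for j in rng.integers(len(_CHAIN_UNITS), size=n_pre - 1)
            )
            suf = "".join(_CHAIN_UNITS[j] for j in rng.integers(len(_CHAIN_UNITS), size=n_suf))
            term = _TERMINAL_UNITS[rng.integers(len(_TERMINAL_UNITS))]
            smi = pre + scaffold + suf + term
            if rng.random() < 0.05:
                smi = smi + "." + _SALTS[rng.integers(len(_SALTS))]
        if Chem.MolFromSmiles(smi) is None:  # grammar should prevent this
            smi = "CCC" + SCAFFOLDS[i % len(SCAFFOLDS)]
        out.append(smi)
    return out


def gen_class_labels(
    molecules: Sequence[tuple[str, str]] | Sequence[str], k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Assign each molecule to one of ``k`` scaffold-defined classes.

    ``molecules`` is a list of SMILES or ``(id, smiles)`` pairs.  Classes are
    the planted ring scaffolds (substructure match, first hit in a fixed
    priority order), so structure-aware fingerprints separate them; molecules
    matching no scaffold get a deterministic pseudo-random class.
    Returns a DataFrame with columns ``drug_id, class``.
    """
    items = [
        m if isinstance(m, tuple) else (f"mol{i}", m) for i, m in enumerate(molecules)
    ]
    if k > len(items):
        raise ValueError(f"k={k} exceeds number of molecules {len(items)}")
    queries = [Chem.MolFromSmarts(s) for s in SCAFFOLDS[:k]]
    rng = np.random.default_rng(seed)
    rows = []
    for mol_id, smi in items:
        mol = Chem.MolFromSmiles(smi)
        label = None
        if mol is not None:
            for ci, q in enumerate(queries):
                if q is not None and mol.HasSubstructMatch(q):
                    label = ci
                    break
        if label is None:
            label = int(rng.integers(k))
        rows.append((mol_id, label))
    return pd.DataFrame(rows, columns=["drug_id", "class"])


# ---------------------------------------------------------------------------
# combination screens


@dataclass
class ScreenSpec:
    """Conditions of a synthetic combination screen.

    ``signal_fraction`` (rho) is the fraction of latent response variance
    explained by structure + cell line; noise is scaled so the planted R^2
    equals rho by construction.  Fix either rho or ``noise_sd``, not both.
    """

    n_molecules: int = 100
    n_cell_lines: int = 5
    n_tuples: int = 2000
    replicate_rate: float = 0.2
    signal_fraction: float | None = 0.5
    noise_sd: float | None = None
    inter_score_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_fraction is not None and self.noise_sd is not None:
            raise ConfigError("fix either signal_fraction or noise_sd, not both")
        if self.signal_fraction is None and self.noise_sd is None:
            raise ConfigError("one of signal_fraction or noise_sd must be set")
        if self.signal_fraction is not None and not 0.0 <= self.signal_fraction <= 1.0:
            raise ConfigError("signal_fraction must lie in [0, 1]")
        if not 0.0 <= self.replicate_rate <= 1.0:
            raise ConfigError("replicate_rate must lie in [0, 1]")


# score-specific affine targets: (mean, sd) on realistic scales
_SCORE_MOMENTS = {
    "css": (40.0, 15.0), "bliss": (0.0, 8.0), "hsa": (0.0, 7.0),
    "loewe": (0.0, 10.0), "zip": (0.0, 8.0),
}
_REPLICATE_SD_FRACTION = 0.1


def _molecule_descriptors(smiles: str) -> np.ndarray:
    """Simple interpretable structure descriptors driving the planted signal."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return np.zeros(8)
    atoms = list(mol.GetAtoms())
    return np.array([
        mol.GetNumHeavyAtoms(),
        sum(a.GetIsAromatic() for a in atoms),
        mol.GetRingInfo().NumRings(),
        sum(a.GetSymbol() == "N" for a in atoms),
        sum(a.GetSymbol() == "O" for a in atoms),
        sum(a.GetSymbol() in ("F", "Cl", "Br", "I") for a in atoms),
        sum(a.GetFormalCharge() != 0 for a in atoms),
        sum(a.GetChiralTag() != Chem.rdchem.ChiralType.CHI_UNSPECIFIED for a in atoms),
    ], dtype=float)


def pair_descriptors(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Order-invariant pair features: elementwise sum and absolute difference."""
    return np.concatenate([desc_a + desc_b, np.abs(desc_a - desc_b)])


def gen_screen(
    molecules: Sequence[tuple[str, str]] | Sequence[str], spec: ScreenSpec
) -> tuple[pd.DataFrame, dict]:
    """Generate a combination screen with a planted structure->score signal.

    Returns ``(table, ground_truth)``.  The table has one row per replicate
    with columns ``drug_a, drug_b, cell_line, replicate, css, bliss, hsa,
    loewe, zip`` (pair order randomized).  ``ground_truth`` carries the
    planted coefficients, cell effects, realized signal fraction, the
    order-invariant pair+cell design matrix aligned to the canonical tuple
    keys, and the per-score prediction ceilings sqrt(rho).
    """
    items = [
        m if isinstance(m, tuple) else (f"M{i:04d}", m) for i, m in enumerate(molecules)
    ]
    if len(items) < 2 or spec.n_cell_lines < 1:
        raise ValueError("need at least 2 molecules and 1 cell line")
    rng = np.random.default_rng(spec.seed)
    ids = [i for i, _ in items]
    desc = np.stack([_molecule_descriptors(s) for _, s in items])
    # z-score descriptor columns so beta draws are comparable
    sd = desc.std(axis=0)
    sd[sd == 0] = 1.0
    desc = (desc - desc.mean(axis=0)) / sd

    m = len(items)
    cells = [f"CL{c:02d}" for c in range(spec.n_cell_lines)]
    n_pairs = m * (m - 1) // 2
    n_combos = n_pairs * spec.n_cell_lines
    if spec.n_tuples > n_combos:
        raise ConfigError(
            f"n_tuples={spec.n_tuples} exceeds available pair x cell combos {n_combos}"
        )
    combo_idx = rng.choice(n_combos, size=spec.n_tuples, replace=False)
    pair_idx, cell_idx = np.divmod(combo_idx, spec.n_cell_lines)
    iu, ju = np.triu_indices(m, k=1)

    beta = rng.normal(0.0, 1.0, size=2 * desc.shape[1])
    cell_effects = rng.normal(0.0, 1.0, size=spec.n_cell_lines)

    design = np.stack([
        pair_descriptors(desc[iu[p]], desc[ju[p]]) for p in pair_idx
    ])
    cell_onehot = np.zeros((spec.n_tuples, spec.n_cell_lines))
    cell_onehot[np.arange(spec.n_tuples), cell_idx] = 1.0

    signal = design @ beta + cell_effects[cell_idx]
    if spec.signal_fraction == 0.0:
        signal = np.zeros_like(signal)
        noise_sd, rho = 1.0, 0.0
    elif spec.noise_sd is not None:
        noise_sd = spec.noise_sd
        v = signal.var()
        rho = float(v / (v + noise_sd**2))
    else:
        rho = float(spec.signal_fraction)
        v = signal.var()
        noise_sd = float(np.sqrt(v * (1.0 - rho) / rho)) if rho < 1.0 else 0.0

    eta = spec.inter_score_correlation
    shared = rng.normal(0.0, noise_sd, size=spec.n_tuples)
    latent_sd = float(np.sqrt(signal.var() + noise_sd**2)) or 1.0

    scores: dict[str, np.ndarray] = {}
    gains, offsets = {}, {}
    for s in SCORES:
        mean, target_sd = _SCORE_MOMENTS[s]
        own = rng.normal(0.0, noise_sd, size=spec.n_tuples)
        noise = np.sqrt(eta) * shared + np.sqrt(1.0 - eta) * own
        a = target_sd / latent_sd
        gains[s], offsets[s] = a, mean
        scores[s] = a * (signal + noise) + mean

    keys = [
        tuple(sorted((ids[iu[p]], ids[ju[p]]))) + (cells[c],)
        for p, c in zip(pair_idx, cell_idx)
    ]
    rows = []
    for t in range(spec.n_tuples):
        a_id, b_id, cell = keys[t]
        if rng.random() < 0.5:  # randomize pair order to exercise canonicalization
            a_id, b_id = b_id, a_id
        n_reps = 2 if rng.random() < spec.replicate_rate else 1
        for rep in range(1, n_reps + 1):
            row = {"drug_a": a_id, "drug_b": b_id, "cell_line": cell, "replicate": rep}
            for s in SCORES:
                rep_sd = _REPLICATE_SD_FRACTION * _SCORE_MOMENTS[s][1]
                row[s] = scores[s][t] + rng.normal(0.0, rep_sd)
            rows.append(row)
    table = pd.DataFrame(rows)

    ground_truth = {
        "beta": beta,
        "cell_effects": dict(zip(cells, cell_effects)),
        "rho": rho,
        "noise_sd": noise_sd,
        "gains": gains,
        "offsets": offsets,
        "ceiling_pcc": float(np.sqrt(rho)),
        "keys": keys,
        "design": np.hstack([design, cell_onehot]),
        "signal": signal,
        "descriptors": {ids[i]: desc[i] for i in range(m)},
    }
    return table, ground_truth
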