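import numpy as np
import pytest
from rdkit import RDLogger

from fpbench import simulate, standardize

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def molecule_items():
    """100 synthetic (id, standardized SMILES) pairs passing the length filter."""
    smiles = simulate.gen_molecules(110, seed=11)
    accepted, _ = standardize.standardize_and_filter(
        [(f"M{i:03d}", s) for i, s in enumerate(smiles)]
    )
    return [(r.id, r.smiles_std) for r in accepted][:100]


@pytest.fixture(scope="session")
def graphs(molecule_items):
    return [
        (mol_id, standardize.MolecularGraph.from_smiles(smi))
        for mol_id, smi in molecule_items[:50]
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
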