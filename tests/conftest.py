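import numpy as np
import pytest

from pharmdock.core_chem import Atom, Bond, MolecularGraph
from pharmdock.fixtures import ToySpec, make_toy_system


def mol_from_smiles(smiles: str):
    """RDKit molecule with explicit hydrogens and one embedded conformer."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 2024
    AllChem.EmbedMolecule(mol, params)
    return mol


def graph_from_smiles(smiles: str) -> MolecularGraph:
    from pharmdock.io import graph_from_rdkit

    return graph_from_rdkit(mol_from_smiles(smiles))


def carbon_chain(n: int, name: str = "chain") -> MolecularGraph:
    """Pseudo n-carbon zigzag chain; interior C-C bonds are the only rotors."""
    atoms = [Atom("C", np.array([1.4 * i, 0.5 * (i % 2), 0.0])) for i in range(n)]
    bonds = [Bond(i, i + 1) for i in range(n - 1)]
    return MolecularGraph(atoms, bonds, name)


@pytest.fixture(scope="session")
def toy():
    """Standard planted-pose system: 2 polar + 2 hydrophobic anchors, rigid ligand."""
    return make_toy_system(ToySpec(n_hbond=2, n_hydrophobic=2, n_rotors=0), seed=1)


@pytest.fixture(scope="session")
def toy_ensemble(toy):
    from pharmdock.ligand_conformers import ConformerEnsemble, conformer_features

    ens = ConformerEnsemble(toy.ligand, [toy.ligand.coords], [0.0])
    ens.features = [conformer_features(toy.ligand, toy.ligand.coords)]
    return ens


@pytest.fixture(scope="session")
def methanol():
    return graph_from_smiles("CO")


@pytest.fixture(scope="session")
def benzene():
    return graph_from_smiles("c1ccccc1")
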