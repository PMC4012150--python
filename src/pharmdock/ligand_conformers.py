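"""Ligand conformer ensembles and per-conformer pharmacophore features.

Docking operates on a pre-generated ensemble of low-energy conformers:
at most ``max_confs`` conformers within ``energy_window`` kcal/mol of the
lowest-energy one, deduplicated by superposed heavy-atom RMSD with a cutoff
that depends on the rotatable-bond count (0.2 / 0.3 / 0.4 A for 0-3 / 4-6 /
>6 rotors). Conformers are read from multi-record SDF/MOL2 files (the
canonical, reproducible path) or generated internally with RDKit's
distance-geometry embedder and MMFF energies.

Hydrophobic atom features of each conformer are condensed by agglomerative
clustering so that cluster centres are at least 2 A apart, which keeps the
clique-matching graph small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_chem import (FeatureType, MolecularGraph, PharmacophorePoint,
                        count_rotatable_bonds, perceive_ligand_features, rmsd)
from .io import graph_from_rdkit, load_ligands

__all__ = [
    "ConformerEnsemble",
    "dedupe_rmsd_cutoff",
    "ensemble_from_file",
    "ensembles_from_file",
    "generate_ensemble",
    "build_ensemble",
    "dedupe_conformers",
    "cluster_ligand_hydrophobes",
    "conformer_features",
]

ENERGY_TAG = "energy_kcal"


@dataclass
class ConformerEnsemble:
    mol: MolecularGraph
    conformers: list[np.ndarray]          # full-atom coordinate sets
    energies: list[float]                 # kcal/mol, ascending
    features: list[list[PharmacophorePoint]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conformers)


def dedupe_rmsd_cutoff(n_rotors: int) -> float:
    """Duplicate-removal RMSD cutoff by rotatable-bond bin."""
    if n_rotors <= 3:
        return 0.2
    if n_rotors <= 6:
        return 0.3
    return 0.4


def conformer_features(mol: MolecularGraph, coords: np.ndarray,
                       min_center_dist: float = 2.0) -> list[PharmacophorePoint]:
    """Perceive features for one conformer with hydrophobes clustered."""
    return cluster_ligand_hydrophobes(perceive_ligand_features(mol, coords),
                                      min_center_dist)


def build_ensemble(mol: MolecularGraph, conformers: list[np.ndarray],
                   energies: list[float], max_confs: int = 100,
                   energy_window: float = 15.0) -> ConformerEnsemble:
    """Apply energy window, cap, dedup and feature perception to raw conformers."""
    if not conformers:
        raise ValueError(f"no conformers supplied for molecule {mol.name!r}")
    order = np.argsort(energies, kind="stable")
    conformers = [np.asarray(conformers[i], float) for i in order]
    energies = [float(energies[i]) for i in order]
    emin = energies[0]
    keep = [i for i, e in enumerate(energies) if e - emin <= energy_window]
    conformers = [conformers[i] for i in keep][:max_confs]
    energies = [energies[i] for i in keep][:max_confs]
    ens = ConformerEnsemble(mol, conformers, energies)
    ens = dedupe_conformers(ens)
    if not ens.conformers:
        raise ValueError(f"no conformers survive filtering for molecule {mol.name!r}")
    ens.features = [conformer_features(mol, c) for c in ens.conformers]
    return ens


def dedupe_conformers(ensemble: ConformerEnsemble) -> ConformerEnsemble:
    """Greedy keep-first duplicate removal on energy-sorted conformers.

    A conformer is dropped when its superposed heavy-atom RMSD to an already
    kept conformer is at or below the rotor-bin cutoff (boundary inclusive),
    so the lowest-energy representative of each duplicate group survives.
    """
    cutoff = dedupe_rmsd_cutoff(count_rotatable_bonds(ensemble.mol))
    heavy = ensemble.mol.heavy_indices()
    kept: list[int] = []
    for i, coords in enumerate(ensemble.conformers):
        dup = False
        for j in kept:
            r = rmsd(coords[heavy], ensemble.conformers[j][heavy], superpose=True)
            if r <= cutoff:
                dup = True
                break
        if not dup:
            kept.append(i)
    return ConformerEnsemble(
        ensemble.mol,
        [ensemble.conformers[i] for i in kept],
        [ensemble.energies[i] for i in kept],
        [ensemble.features[i] for i in kept] if ensemble.features else [],
    )


def ensembles_from_file(path: str | Path, max_confs: int = 100,
                        energy_window: float = 15.0) -> list[ConformerEnsemble]:
    """Read a ligand library; consecutive same-titled records are conformers.

    Per-conformer internal energies are taken from the ``energy_kcal`` SD tag
    (0.0 when absent, which disables the window for that file).
    """
    out = []
    for group in load_ligands(path):
        mol = graph_from_rdkit(group[0])
        conformers, energies = [], []
        for m in group:
            g = graph_from_rdkit(m)
            conformers.append(g.coords)
            e = float(m.GetProp(ENERGY_TAG)) if m.HasProp(ENERGY_TAG) else 0.0
            energies.append(e)
        out.append(build_ensemble(mol, conformers, energies, max_confs, energy_window))
    return out


def ensemble_from_file(path: str | Path, **kw) -> ConformerEnsemble:
    ensembles = ensembles_from_file(path, **kw)
    if len(ensembles) != 1:
        raise ValueError(f"expected one molecule in {path}, found {len(ensembles)}")
    return ensembles[0]


def generate_ensemble(rdmol, max_confs: int = 100, energy_window: float = 15.0,
                      seed: int = 7, n_embed: int | None = None) -> ConformerEnsemble:
    """Internal fallback generator: ETKDG embedding + MMFF94 energies."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(rdmol, addCoords=True) if not _has_explicit_h(rdmol) else Chem.Mol(rdmol)
    n_embed = n_embed or max(2 * max_confs, 20)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31)
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=n_embed, params=params)
    if not cids:
        raise ValueError("conformer embedding failed")
    energies = []
    props = AllChem.MMFFGetMoleculeProperties(mol)
    for cid in cids:
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            ff.Minimize(maxIts=200)
            energies.append(ff.CalcEnergy())
        else:
            energies.append(0.0)
    graph = graph_from_rdkit(mol, conf_id=cids[0])
    conformers = []
    for cid in cids:
        conf = mol.GetConformer(cid)
        conformers.append(np.array([[conf.GetAtomPosition(i).x,
                                     conf.GetAtomPosition(i).y,
                                     conf.GetAtomPosition(i).z]
                                    for i in range(mol.GetNumAtoms())]))
    return build_ensemble(graph, conformers, energies, max_confs, energy_window)


def _has_explicit_h(rdmol) -> bool:
    return any(a.GetAtomicNum() == 1 for a in rdmol.GetAtoms())


def cluster_ligand_hydrophobes(features: list[PharmacophorePoint],
                               min_center_dist: float = 2.0) -> list[PharmacophorePoint]:
    """Merge hydrophobic candidate atoms until all cluster centres are at
    least ``min_center_dist`` apart; non-hydrophobic features pass through."""
    hydro = [f for f in features if f.type == FeatureType.HYDROPHOBIC]
    rest = [f for f in features if f.type != FeatureType.HYDROPHOBIC]
    if len(hydro) <= 1:
        return rest + hydro

    clusters = [[f.position.copy()] for f in hydro]

    def centre(members):
        return np.mean(members, axis=0)

    while len(clusters) > 1:
        centres = np.array([centre(c) for c in clusters])
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= min_center_dist:
            break
        a, b = min(i, j), max(i, j)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]

    merged = [PharmacophorePoint(FeatureType.HYDROPHOBIC, centre(c), weight=float(len(c)))
              for c in clusters]
    return rest + merged
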