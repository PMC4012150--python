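"""File input/output: SDF and MOL2 ligands, PDB receptors, pose writing.

Ligand chemistry (bond orders, aromaticity, formal charges) is delegated to
RDKit; receptor PDB files are parsed with Biopython and bonds inferred from
inter-atomic distances, which is robust for protonated protein structures
where connectivity records are absent.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .core_chem import Atom, Bond, MolecularGraph

__all__ = [
    "graph_from_rdkit",
    "graph_to_rdkit",
    "load_ligands",
    "load_receptor_pdb",
    "receptor_from_pdb_block",
    "write_poses_sdf",
]

# covalent radii for distance-based bond inference in PDB receptors
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


def graph_from_rdkit(mol, conf_id: int = -1) -> MolecularGraph:
    """Convert an RDKit molecule (with explicit hydrogens) to a MolecularGraph."""
    from rdkit import Chem

    conf = mol.GetConformer(conf_id)
    atoms = []
    for a in mol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), np.array([p.x, p.y, p.z]),
                          formal_charge=a.GetFormalCharge()))
    ri = mol.GetRingInfo()
    try:
        ri.NumRings()
    except RuntimeError:  # unsanitized molecule: perceive rings cheaply
        Chem.FastFindRings(mol)
        ri = mol.GetRingInfo()
    bonds = []
    for b in mol.GetBonds():
        order = b.GetBondTypeAsDouble()
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                          order=1.0 if b.GetIsAromatic() else order,
                          aromatic=b.GetIsAromatic(),
                          in_ring=ri.NumBondRings(b.GetIdx()) > 0))
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return MolecularGraph(atoms, bonds, name)


def graph_to_rdkit(graph: MolecularGraph, coords: np.ndarray | None = None):
    """Build an (unsanitized) RDKit molecule from a MolecularGraph, for writing."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in graph.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                 3.0: Chem.BondType.TRIPLE}
    for b in graph.bonds:
        bt = Chem.BondType.AROMATIC if b.aromatic else order_map.get(b.order, Chem.BondType.SINGLE)
        rw.AddBond(b.i, b.j, bt)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(graph.atoms))
    xyz = graph.coords if coords is None else np.asarray(coords, float)
    for i, p in enumerate(xyz):
        conf.SetAtomPosition(i, Point3D(*map(float, p)))
    mol.AddConformer(conf, assignId=True)
    mol.SetProp("_Name", graph.name)
    return mol


def _rdkit_mols_from_file(path: str | Path):
    from rdkit import Chem

    def _sanitize_or_raw(mol):
        """Prefer full sanitization; fall back to the raw molecule so that
        synthetic pseudo-ligands with unphysical valences still load."""
        if mol is None:
            return None
        try:
            clean = Chem.Mol(mol)
            Chem.SanitizeMol(clean)
            return clean
        except Exception:
            Chem.FastFindRings(mol)
            return mol

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mols = [_sanitize_or_raw(m) for m in supplier]
        return [m for m in mols if m is not None]
    if suffix == ".mol2":
        blocks, current = [], []
        for line in path.read_text().splitlines(keepends=True):
            if line.startswith("@<TRIPOS>MOLECULE") and current:
                blocks.append("".join(current))
                current = []
            current.append(line)
        if current:
            blocks.append("".join(current))
        mols = []
        for blk in blocks:
            m = Chem.MolFromMol2Block(blk, removeHs=False, sanitize=True)
            if m is not None:
                mols.append(m)
        return mols
    raise ValueError(f"unsupported ligand format: {path.suffix!r} (use .sdf or .mol2)")


def load_ligands(path: str | Path) -> list[list]:
    """Read a ligand library; consecutive records sharing a title are grouped
    as conformers of one molecule. Returns a list of RDKit-molecule groups."""
    mols = _rdkit_mols_from_file(path)
    groups: list[list] = []
    last_name = object()
    for m in mols:
        name = m.GetProp("_Name") if m.HasProp("_Name") else ""
        if name == last_name and name != "":
            groups[-1].append(m)
        else:
            groups.append([m])
        last_name = name
    return groups


def receptor_from_pdb_block(text: str, name: str = "receptor") -> MolecularGraph:
    """Parse a PDB text block into a receptor graph; bonds inferred by distance."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name, _io.StringIO(text))
    atoms, het_flags = [], []
    for residue in structure.get_residues():
        is_het = residue.id[0].strip() != ""
        if residue.id[0] == "W":  # waters excluded
            continue
        for at in residue.get_atoms():
            elem = (at.element or "").strip().capitalize()
            if not elem:
                continue
            atoms.append(Atom(elem, np.array(at.coord, dtype=float), hetero=is_het))
            het_flags.append(is_het)
    if not atoms:
        raise ValueError("no atoms parsed from PDB input")
    bonds = _infer_bonds(atoms)
    return MolecularGraph(atoms, bonds, name)


def load_receptor_pdb(path: str | Path) -> MolecularGraph:
    return receptor_from_pdb_block(Path(path).read_text(), Path(path).stem)


def _infer_bonds(atoms: list[Atom]) -> list[Bond]:
    from scipy.spatial import cKDTree

    coords = np.array([a.position for a in atoms])
    tree = cKDTree(coords)
    bonds = []
    for i, j in sorted(tree.query_pairs(r=2.6)):
        ri = _COVALENT_RADII.get(atoms[i].element, 0.77)
        rj = _COVALENT_RADII.get(atoms[j].element, 0.77)
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= ri + rj + 0.45:
            if atoms[i].element == "H" and atoms[j].element == "H":
                continue
            bonds.append(Bond(i, j))
    return bonds


def write_poses_sdf(path: str | Path, graph: MolecularGraph, poses,
                    extra_tags: dict | None = None) -> None:
    """Write placed poses as a multi-record SDF with score SD tags."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for rank, pose in enumerate(poses, start=1):
        mol = graph_to_rdkit(graph, pose.coordinates)
        mol.SetProp("_Name", graph.name or "ligand")
        mol.SetProp("pharm_score", f"{pose.pharm_score:.4f}" if pose.pharm_score is not None else "")
        mol.SetProp("plp_energy", f"{pose.plp_energy:.4f}" if pose.plp_energy is not None else "")
        mol.SetProp("rank", str(rank))
        mol.SetProp("clique_size", str(len(pose.clique)))
        for k, v in (extra_tags or {}).items():
            mol.SetProp(k, str(v))
        writer.write(mol)
    writer.close()
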