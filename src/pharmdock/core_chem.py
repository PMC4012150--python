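"""Molecular data model and perception rules.

Holds the lightweight molecular graph used throughout the docking pipeline,
pharmacophore feature perception for ligands, the four-class atom typing used
by the piecewise-linear pairwise (PLP) scoring function, rotatable-bond
counting, and RMSD utilities (in-place and Kabsch-superposed).

Molecules arrive protonated: hydrogen placement, tautomer and protonation
assignment are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureType",
    "PLPAtomClass",
    "Atom",
    "Bond",
    "MolecularGraph",
    "PharmacophorePoint",
    "perceive_ligand_features",
    "assign_plp_class",
    "classify_pair_interaction",
    "count_rotatable_bonds",
    "rmsd",
    "kabsch",
    "VDW_RADII",
]

# Bondi-style van der Waals radii (Angstrom); fallback 1.7 for exotic elements.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# Valence-electron counts used for lone-pair accounting.
_VALENCE_ELECTRONS = {"N": 5, "O": 6, "S": 6, "P": 5, "F": 7, "Cl": 7, "Br": 7, "I": 7}

_HBOND_ELEMENTS = frozenset({"N", "O", "S"})


class FeatureType(Enum):
    """Pharmacophore feature types shared by ligand and protein-based models."""

    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"
    HYDROPHOBIC = "HYDROPHOBIC"
    AROMATIC = "AROMATIC"
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    FORBIDDEN = "FORBIDDEN"


class PLPAtomClass(Enum):
    """Four-class heavy-atom typing for the PLP pair potential."""

    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"
    BOTH = "BOTH"
    NONPOLAR = "NONPOLAR"


@dataclass
class Atom:
    element: str
    position: np.ndarray
    formal_charge: int = 0
    is_polar_hydrogen: bool = False
    vdw_radius: float = 0.0
    hetero: bool = False  # cofactor / HETATM: steric obstacle only

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be 3 finite components")
        if self.vdw_radius <= 0.0:
            self.vdw_radius = VDW_RADII.get(self.element, 1.70)


@dataclass
class Bond:
    i: int
    j: int
    order: float = 1.0
    aromatic: bool = False
    in_ring: bool = False


@dataclass
class MolecularGraph:
    """Ordered atoms plus bonds; the in-memory molecule for the whole pipeline."""

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"invalid bond ({b.i},{b.j}) for {n} atoms")
        if not self.heavy_indices():
            raise ValueError("molecule must contain at least one heavy atom")
        self._mark_polar_hydrogens()

    def _mark_polar_hydrogens(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.element == "H":
                a.is_polar_hydrogen = any(
                    self.atoms[j].element in _HBOND_ELEMENTS for j in self.neighbors(i)
                )

    # -- topology helpers -------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices()]

    def with_coords(self, coords: np.ndarray) -> "MolecularGraph":
        """Copy of the graph with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.element, coords[i].copy(), a.formal_charge,
                 a.is_polar_hydrogen, a.vdw_radius, a.hetero)
            for i, a in enumerate(self.atoms)
        ]
        return MolecularGraph(atoms, list(self.bonds), self.name)

    # -- electronic bookkeeping -------------------------------------------

    def bond_order_sum(self, i: int) -> float:
        total = 0.0
        for b in self.bonds:
            if i in (b.i, b.j):
                total += 1.5 if b.aromatic else b.order
        return total

    def lone_pairs(self, i: int) -> int:
        """Lone pairs by standard valence accounting; 0 for elements without a table entry."""
        a = self.atoms[i]
        ve = _VALENCE_ELECTRONS.get(a.element)
        if ve is None:
            return 0
        nonbonding = ve - a.formal_charge - self.bond_order_sum(i)
        return max(int(nonbonding // 2), 0)

    def is_acceptor_atom(self, i: int) -> bool:
        """O/N/S with at least one available lone pair (excludes pyrrole-type and quaternary N)."""
        return self.atoms[i].element in _HBOND_ELEMENTS and self.lone_pairs(i) >= 1

    def is_donor_heavy_atom(self, i: int) -> bool:
        """O/N/S bearing at least one (polar) hydrogen."""
        if self.atoms[i].element not in _HBOND_ELEMENTS:
            return False
        return any(self.atoms[j].element == "H" for j in self.neighbors(i))

    def aromatic_rings(self) -> list[list[int]]:
        """Rings of aromatic bonds, as atom-index cycles (minimum cycle basis)."""
        import networkx as nx

        g = nx.Graph()
        for b in self.bonds:
            if b.aromatic:
                g.add_edge(b.i, b.j)
        if g.number_of_edges() == 0:
            return []
        return [sorted(c) for c in nx.minimum_cycle_basis(g)]


@dataclass
class PharmacophorePoint:
    """A typed 3D feature; shared by ligand features and protein-based models."""

    type: FeatureType
    position: np.ndarray
    weight: float = 0.0
    patch_id: int = -1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.weight < 0:
            raise ValueError("pharmacophore weight must be >= 0")


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def perceive_ligand_features(
    mol: MolecularGraph, conformer_coords: np.ndarray | None = None
) -> list[PharmacophorePoint]:
    """Perceive pharmacophore features of one ligand conformer.

    Donors are polar hydrogens bonded to O/N/S; acceptors are O/N/S atoms with
    a lone pair; hydrophobic candidates are heavy atoms that are neither
    donors/acceptors nor directly bonded to one; aromatic features sit at ring
    centroids; ionic features at the centroid of the formally charged group
    (charged atom plus its hydrogens).

    Hydrophobic candidates are returned per atom; cluster them with
    :func:`pharmdock.ligand_conformers.cluster_ligand_hydrophobes` before
    matching.
    """
    coords = mol.coords if conformer_coords is None else np.asarray(conformer_coords, float)
    if coords.shape != (len(mol.atoms), 3):
        raise ValueError("conformer coordinates must cover all atoms")
    n_h = sum(1 for a in mol.atoms if a.element == "H")
    if n_h == 0 and any(a.element in _HBOND_ELEMENTS for a in mol.atoms):
        raise ValueError(
            f"molecule {mol.name!r} has no explicit hydrogens; "
            "protonate the structure before feature perception"
        )

    feats: list[PharmacophorePoint] = []
    donor_or_acceptor: set[int] = set()
    for i, a in enumerate(mol.atoms):
        if a.element == "H":
            continue
        if mol.is_donor_heavy_atom(i) or mol.is_acceptor_atom(i):
            donor_or_acceptor.add(i)

    # donors: polar hydrogens on O/N/S
    for i, a in enumerate(mol.atoms):
        if a.element == "H" and a.is_polar_hydrogen:
            feats.append(PharmacophorePoint(FeatureType.DONOR, coords[i]))
    # acceptors
    for i in sorted(donor_or_acceptor):
        if mol.is_acceptor_atom(i):
            feats.append(PharmacophorePoint(FeatureType.ACCEPTOR, coords[i]))
    # hydrophobic candidates
    for i, a in enumerate(mol.atoms):
        if a.element == "H" or i in donor_or_acceptor:
            continue
        if any(j in donor_or_acceptor for j in mol.neighbors(i)):
            continue
        feats.append(PharmacophorePoint(FeatureType.HYDROPHOBIC, coords[i]))
    # aromatic ring centroids
    for ring in mol.aromatic_rings():
        feats.append(PharmacophorePoint(FeatureType.AROMATIC, coords[ring].mean(axis=0)))
    # ionic groups: charged atom + bonded hydrogens define the group centroid
    for i, a in enumerate(mol.atoms):
        if a.element == "H" or a.formal_charge == 0:
            continue
        group = [i] + [j for j in mol.neighbors(i) if mol.atoms[j].element == "H"]
        centroid = coords[group].mean(axis=0)
        ftype = FeatureType.POSITIVE if a.formal_charge > 0 else FeatureType.NEGATIVE
        feats.append(PharmacophorePoint(ftype, centroid))
    return feats


def assign_plp_class(atom_index: int, mol: MolecularGraph) -> PLPAtomClass:
    """Assign the PLP four-class type to a heavy atom.

    O/N/S with both an attached hydrogen and a lone pair type as BOTH; with a
    lone pair only as ACCEPTOR; with a hydrogen but no lone pair as DONOR.
    Everything else is NONPOLAR. Hydrogens carry no class.
    """
    a = mol.atoms[atom_index]
    if a.element == "H":
        raise ValueError("PLP classes are assigned to heavy atoms only")
    if a.element not in _HBOND_ELEMENTS:
        return PLPAtomClass.NONPOLAR
    has_h = any(mol.atoms[j].element == "H" for j in mol.neighbors(atom_index))
    has_lp = mol.lone_pairs(atom_index) >= 1
    if has_h and has_lp:
        return PLPAtomClass.BOTH
    if has_h:
        return PLPAtomClass.DONOR
    if has_lp:
        return PLPAtomClass.ACCEPTOR
    return PLPAtomClass.NONPOLAR


def classify_pair_interaction(a: PLPAtomClass, b: PLPAtomClass) -> str:
    """'HBOND' iff one partner can donate and the other accept; else 'STERIC'."""
    donates = {PLPAtomClass.DONOR, PLPAtomClass.BOTH}
    accepts = {PLPAtomClass.ACCEPTOR, PLPAtomClass.BOTH}
    if (a in donates and b in accepts) or (b in donates and a in accepts):
        return "HBOND"
    return "STERIC"


def count_rotatable_bonds(mol: MolecularGraph) -> int:
    """Strict rotatable-bond count.

    Non-ring single bonds between heavy atoms where each end has at least one
    other heavy neighbor; amide C-N bonds are excluded.
    """
    heavy = set(mol.heavy_indices())
    n = 0
    for b in mol.bonds:
        if b.in_ring or b.aromatic or b.order != 1.0:
            continue
        if b.i not in heavy or b.j not in heavy:
            continue
        ni = [k for k in mol.neighbors(b.i) if k != b.j and k in heavy]
        nj = [k for k in mol.neighbors(b.j) if k != b.i and k in heavy]
        if not ni or not nj:
            continue
        if _is_amide(mol, b.i, b.j) or _is_amide(mol, b.j, b.i):
            continue
        n += 1
    return n


def _is_amide(mol: MolecularGraph, c: int, nitrogen: int) -> bool:
    if mol.atoms[c].element != "C" or mol.atoms[nitrogen].element != "N":
        return False
    for b in mol.bonds:
        if c in (b.i, b.j) and b.order == 2.0:
            other = b.j if b.i == c else b.i
            if mol.atoms[other].element == "O":
                return True
    return False


# ---------------------------------------------------------------------------
# RMSD / Kabsch
# ---------------------------------------------------------------------------

def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal proper rotation R and translation t with dst ~ src @ R.T + t.

    Reflections are suppressed (det(R) = +1). Returns (R, t, residual RMSD).
    Raises on degenerate (collinear or coincident) point sets of size >= 3.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must be matching (n,3) arrays")
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    p = src - cs
    q = dst - cd
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    if src.shape[0] >= 3:
        scale = max(np.linalg.norm(p), 1.0)
        if s[1] / scale**2 < 1e-10:
            raise ValueError("degenerate (collinear) point set: rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = cd - rot @ cs
    moved = src @ rot.T + t
    residual = float(np.sqrt(np.mean(np.sum((moved - dst) ** 2, axis=1))))
    return rot, t, residual


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between two equally ordered coordinate sets.

    With ``superpose=True`` the optimal rigid superposition (no reflection) is
    applied first; otherwise the deviation is measured in place.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError(f"atom-count mismatch: {a.shape} vs {b.shape}")
    if superpose:
        try:
            _, _, res = kabsch(a, b)
            return res
        except ValueError:
            # collinear sets: fall back to centred comparison about the best axis
            pass
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
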