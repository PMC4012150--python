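"""Pose sampling by clique matching of ligand features to protein pharmacophores.

Each type-compatible (ligand feature, protein point) pair is a node of a
correspondence graph; two nodes are connected when they share no ligand
feature or protein point and the ligand-side and protein-side edge lengths
agree within a 0.3 A tolerance. Maximal cliques of at least three nodes
(Bron-Kerbosch with pivoting) define geometrically consistent multi-point
matches. The ligand conformer is rigidly placed by Kabsch superposition of
its clique features onto the matching protein points, and placements in which
more than 10% of the ligand heavy atoms fall within 1.3 A of a forbidden
point are rejected as clashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_chem import FeatureType, MolecularGraph, PharmacophorePoint, kabsch
from .protein_pharm import PharmacophoreModel

__all__ = [
    "MatchNode",
    "CorrespondenceGraph",
    "Pose",
    "build_match_graph",
    "enumerate_cliques",
    "kabsch_superpose",
    "place_and_filter",
    "sample_poses",
    "EDGE_TOLERANCE",
    "CLASH_RADIUS",
    "CLASH_FRACTION",
]

log = logging.getLogger(__name__)

EDGE_TOLERANCE = 0.3   # A, on correspondence-graph edge lengths
CLASH_RADIUS = 1.3     # A, ligand heavy atom to forbidden point
CLASH_FRACTION = 0.10  # reject when MORE than this fraction overlaps
MIN_CLIQUE = 3
SAMPLING_TYPES = (FeatureType.DONOR, FeatureType.ACCEPTOR, FeatureType.HYDROPHOBIC)


@dataclass(frozen=True)
class MatchNode:
    ligand_feature_index: int
    protein_point_index: int
    type: FeatureType


@dataclass
class CorrespondenceGraph:
    nodes: list[MatchNode]
    adjacency: np.ndarray  # boolean (n, n), symmetric, zero diagonal
    ligand_positions: np.ndarray
    protein_positions: np.ndarray

    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(eq=False)
class Pose:
    conformer_index: int
    coordinates: np.ndarray
    clique: tuple[MatchNode, ...]
    pharm_score: float | None = None
    plp_energy: float | None = None
    pose_index: int = -1
    breakdown: object = None


def build_match_graph(features: list[PharmacophorePoint], model: PharmacophoreModel,
                      tol: float = EDGE_TOLERANCE) -> CorrespondenceGraph:
    """Correspondence graph of one conformer's features against the sampling model.

    Only donor, acceptor and hydrophobic features participate; a ligand
    feature pairs with protein points of the same type label (the protein
    model is already complementarity-resolved).
    """
    nodes: list[MatchNode] = []
    lig_pos, prot_pos = [], []
    for li, f in enumerate(features):
        if f.type not in SAMPLING_TYPES:
            continue
        for pi, p in enumerate(model.points):
            if p.type != f.type:
                continue
            nodes.append(MatchNode(li, pi, f.type))
            lig_pos.append(f.position)
            prot_pos.append(p.position)
    n = len(nodes)
    lig = np.array(lig_pos) if lig_pos else np.empty((0, 3))
    prot = np.array(prot_pos) if prot_pos else np.empty((0, 3))
    adj = np.zeros((n, n), dtype=bool)
    if n > 1:
        dl = np.linalg.norm(lig[:, None] - lig[None, :], axis=2)
        dp = np.linalg.norm(prot[:, None] - prot[None, :], axis=2)
        compatible = np.abs(dl - dp) <= tol
        li_idx = np.array([nd.ligand_feature_index for nd in nodes])
        pi_idx = np.array([nd.protein_point_index for nd in nodes])
        distinct = (li_idx[:, None] != li_idx[None, :]) & (pi_idx[:, None] != pi_idx[None, :])
        adj = compatible & distinct
        np.fill_diagonal(adj, False)
    return CorrespondenceGraph(nodes, adj, lig, prot)


def enumerate_cliques(graph: CorrespondenceGraph, min_size: int = MIN_CLIQUE,
                      max_cliques: int = 50_000) -> list[tuple[int, ...]]:
    """All maximal cliques of size >= min_size, via Bron-Kerbosch with pivoting.

    Output is deterministic: cliques sorted by size (descending) then
    lexicographically, truncated at ``max_cliques`` if necessary.
    """
    n = len(graph.nodes)
    if graph.adjacency.shape != (n, n):
        raise ValueError("node/adjacency inconsistency")
    adj = [set(np.flatnonzero(graph.adjacency[i]).tolist()) for i in range(n)]
    cliques: list[tuple[int, ...]] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            if len(r) >= min_size:
                cliques.append(tuple(sorted(r)))
            return
        pivot = max(p | x, key=lambda v: len(adj[v] & p))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(range(n)), set())
    cliques.sort(key=lambda c: (-len(c), c))
    if len(cliques) > max_cliques:
        log.warning("clique cap hit: %d cliques truncated to %d", len(cliques), max_cliques)
        cliques = cliques[:max_cliques]
    return cliques


def kabsch_superpose(src: np.ndarray, dst: np.ndarray):
    """Optimal proper rigid transform aligning src onto dst; see core_chem.kabsch."""
    return kabsch(src, dst)


def place_and_filter(conformer_coords: np.ndarray, mol: MolecularGraph,
                     clique: tuple[int, ...], graph: CorrespondenceGraph,
                     model: PharmacophoreModel, conformer_index: int = 0,
                     forbidden_tree=None) -> Pose | None:
    """Rigidly place the conformer by its clique and apply the clash filter.

    Returns None for degenerate clique geometry or when more than 10% of the
    heavy atoms lie within 1.3 A of a forbidden point.
    """
    idx = list(clique)
    src = graph.ligand_positions[idx]
    dst = graph.protein_positions[idx]
    try:
        rot, t, _ = kabsch(src, dst)
    except ValueError:
        log.debug("degenerate clique geometry skipped: %s", clique)
        return None
    placed = np.asarray(conformer_coords, float) @ rot.T + t

    heavy = mol.heavy_indices()
    if len(model.forbidden):
        if forbidden_tree is None:
            from scipy.spatial import cKDTree

            forbidden_tree = cKDTree(model.forbidden)
        d, _ = forbidden_tree.query(placed[heavy])
        n_overlap = int(np.sum(d <= CLASH_RADIUS))
        if n_overlap > CLASH_FRACTION * len(heavy):
            return None
    return Pose(conformer_index, placed, tuple(graph.nodes[i] for i in idx))


def sample_poses(ensemble, model: PharmacophoreModel, tol: float = EDGE_TOLERANCE,
                 max_cliques: int = 50_000, dedup_rmsd: float = 0.5) -> list[Pose]:
    """Full sampling pass over a conformer ensemble.

    Near-duplicate poses (in-place heavy-atom RMSD <= ``dedup_rmsd``) arising
    from different cliques are merged, keeping the pose with the larger clique.
    """
    from scipy.spatial import cKDTree

    forbidden_tree = cKDTree(model.forbidden) if len(model.forbidden) else None
    heavy = ensemble.mol.heavy_indices()
    poses: list[Pose] = []
    for ci, coords in enumerate(ensemble.conformers):
        graph = build_match_graph(ensemble.features[ci], model, tol)
        for clique in enumerate_cliques(graph, max_cliques=max_cliques):
            pose = place_and_filter(coords, ensemble.mol, clique, graph, model,
                                    conformer_index=ci, forbidden_tree=forbidden_tree)
            if pose is None:
                continue
            dup = False
            ph = pose.coordinates[heavy]
            for kept in poses:
                if kept.conformer_index != ci:
                    continue
                if np.sqrt(np.mean(np.sum((ph - kept.coordinates[heavy]) ** 2, axis=1))) <= dedup_rmsd:
                    dup = True
                    if len(pose.clique) > len(kept.clique):
                        kept.coordinates = pose.coordinates
                        kept.clique = pose.clique
                    break
            if not dup:
                poses.append(pose)
    for i, p in enumerate(poses):
        p.pose_index = i
    return poses
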