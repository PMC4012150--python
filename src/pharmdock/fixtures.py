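"""Deterministic synthetic test systems and brute-force oracles.

A toy system is a pseudo-atom receptor pocket (typed donor, acceptor and
apolar sites on a cradle geometry) plus a pseudo-ligand constructed so that
its pharmacophore features coincide exactly with points of the pocket's own
sampling pharmacophore model. The constructed ligand coordinates are the
planted pose; docking the rigidly displaced conformer back into the pocket
must recover it. Everything is a pure function of (spec, seed).

These systems are chemically simplified stand-ins for real protein-ligand
complexes: bond lengths and valences of the pseudo-molecules are not
physically meaningful, only their typed geometry matters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core_chem import (Atom, Bond, FeatureType, MolecularGraph,
                        PharmacophorePoint)
from .pharm_rank import WEIGHTS, _CLASS_OF, f_r
from .pose_sampler import CorrespondenceGraph
from .protein_pharm import (BindingSiteBox, PharmacophoreModel, PharmGenConfig,
                            build_models)

__all__ = ["ToySpec", "ToySystem", "make_toy_system", "brute_force_cliques",
           "brute_force_pharm_score", "receptor_to_pdb", "MINI_PDB"]


@dataclass(frozen=True)
class ToySpec:
    n_hbond: int = 2          # polar anchor units (alternating donor/acceptor)
    n_hydrophobic: int = 2    # hydrophobic anchor targets (apolar tripods)
    n_rotors: int = 0         # rotatable bonds in the pseudo-ligand (0..3)
    decoy_sites: int = 0      # replicate the polar/tripod motif in a decoy sub-pocket


@dataclass
class ToySystem:
    receptor: MolecularGraph
    ligand: MolecularGraph            # coordinates in the (displaced) input frame
    planted_pose: np.ndarray          # full-atom coordinates in the receptor frame
    box: BindingSiteBox
    sampling_model: PharmacophoreModel
    ranking_model: PharmacophoreModel
    anchor_points: list[PharmacophorePoint]  # model points the ligand was built on
    seed: int
    config: PharmGenConfig = field(default_factory=PharmGenConfig)


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _build_receptor(spec: ToySpec, offset=np.zeros(3)) -> tuple[list[Atom], list[Bond], list[np.ndarray]]:
    """Pocket atoms around the given offset; returns atoms, bonds and the
    intended feature target positions (donor, acceptor, hydrophobic...)."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    targets: list[tuple[FeatureType, np.ndarray]] = []

    polar_layout = [
        (np.array([2.1, 0.0, 0.2]), _unit([1.0, 0.15, 0.1])),
        (np.array([-2.0, 1.1, 0.0]), _unit([-1.0, 0.35, 0.05])),
        (np.array([0.1, 2.3, 0.3]), _unit([0.1, 1.0, 0.2])),
        (np.array([-0.4, -0.5, 2.4]), _unit([-0.2, -0.3, 1.0])),
    ]
    if spec.n_hbond > len(polar_layout):
        raise ValueError("infeasible spec: too many polar units")
    for k in range(spec.n_hbond):
        pos, u = polar_layout[k]
        pos = pos + offset
        if k % 2 == 0:  # donor target: protein acceptor (carbonyl-like O with C anchor)
            o = pos + 1.85 * u
            c = o + 1.23 * u
            i0 = len(atoms)
            atoms.append(Atom("O", o))
            atoms.append(Atom("C", c))
            bonds.append(Bond(i0, i0 + 1, order=2.0))
            targets.append((FeatureType.DONOR, pos))
        else:       # acceptor target: protein donor (N-H pointing at the pocket)
            h = pos + 1.85 * u
            n = h + 1.00 * u
            i0 = len(atoms)
            atoms.append(Atom("H", h))
            atoms.append(Atom("N", n))
            bonds.append(Bond(i0, i0 + 1))
            targets.append((FeatureType.ACCEPTOR, pos))

    hydro_layout = [np.array([0.4, -1.7, -0.4]), np.array([3.2, -1.9, -0.3]),
                    np.array([-2.6, -1.5, -0.6])]
    if spec.n_hydrophobic > len(hydro_layout):
        raise ValueError("infeasible spec: too many hydrophobic units")
    tilt = math.radians(42.0)
    for k in range(spec.n_hydrophobic):
        centre = hydro_layout[k] + offset
        for m in range(3):  # apolar tripod cradling the target from below
            phi = math.radians(120.0 * m + 20.0 * k)
            d = np.array([math.sin(tilt) * math.cos(phi),
                          math.sin(tilt) * math.sin(phi),
                          -math.cos(tilt)])
            atoms.append(Atom("C", centre + 3.55 * d))
        targets.append((FeatureType.HYDROPHOBIC, centre))
    return atoms, bonds, targets


def make_toy_system(spec: ToySpec = ToySpec(), seed: int = 0,
                    config: PharmGenConfig | None = None) -> ToySystem:
    """Construct a pocket, derive its pharmacophore model, and plant a
    pseudo-ligand whose features sit exactly on model points."""
    if spec.n_hbond + spec.n_hydrophobic < 3:
        raise ValueError("infeasible spec: need at least 3 anchor features for a clique")
    if not 0 <= spec.n_rotors <= 3:
        raise ValueError("infeasible spec: n_rotors must be in 0..3")
    rng = np.random.default_rng(seed)
    cfg = config or PharmGenConfig()

    atoms, bonds, targets = _build_receptor(spec)
    if spec.decoy_sites > 0:
        decoy_spec = ToySpec(n_hbond=min(spec.n_hbond, 2),
                             n_hydrophobic=min(spec.n_hydrophobic, 1))
        d_atoms, d_bonds, _ = _build_receptor(decoy_spec, offset=np.array([0.0, 12.0, 0.0]))
        base = len(atoms)
        atoms.extend(d_atoms)
        bonds.extend(Bond(b.i + base, b.j + base, b.order, b.aromatic, b.in_ring)
                     for b in d_bonds)
    receptor = MolecularGraph(atoms, bonds, name="toy-pocket")

    tpos = np.array([p for _, p in targets])
    box = BindingSiteBox(tpos.min(axis=0) - 3.0, tpos.max(axis=0) + 3.0,
                         provenance="reference_ligand")
    if spec.decoy_sites > 0:
        box = BindingSiteBox(box.min_corner, box.max_corner + np.array([0.0, 12.0, 0.0]),
                             provenance="reference_ligand")
    sampling, ranking = build_models(receptor, box, cfg)

    # snap each intended target to the nearest sampling-model point of its
    # type that keeps a heavy atom placed there clear of the forbidden shell
    from scipy.spatial import cKDTree

    ftree = cKDTree(sampling.forbidden) if len(sampling.forbidden) else None
    anchors: list[PharmacophorePoint] = []
    used: set[int] = set()
    for ftype, pos in targets:
        cands = [(i, p) for i, p in enumerate(sampling.points)
                 if p.type == ftype and i not in used]
        if not cands:
            raise ValueError(f"pocket produced no {ftype.name} model point")
        dists = [np.linalg.norm(p.position - pos) for _, p in cands]
        order = np.argsort(dists)
        chosen = None
        for oi in order:
            i, p = cands[oi]
            if ftype == FeatureType.HYDROPHOBIC and any(
                    a.type == FeatureType.HYDROPHOBIC
                    and np.linalg.norm(a.position - p.position) < 2.2 for a in anchors):
                continue
            # donor anchors host a ligand hydrogen, all others a heavy atom
            if (ftype != FeatureType.DONOR and ftree is not None
                    and ftree.query(p.position)[0] <= 1.45):
                continue
            chosen = (i, p)
            break
        if chosen is None:
            raise ValueError(f"no clash-free {ftype.name} anchor available")
        used.add(chosen[0])
        anchors.append(chosen[1])

    ligand, planted = _build_ligand(spec, anchors, rng)

    # planted pose must be clash-free (invariant of the construction)
    from scipy.spatial import cKDTree

    heavy = ligand.heavy_indices()
    if len(sampling.forbidden):
        d, _ = cKDTree(sampling.forbidden).query(planted[heavy])
        n_overlap = int(np.sum(d <= 1.3))
        if n_overlap > 0.10 * len(heavy):
            raise ValueError("constructed planted pose clashes with the pocket")

    # hand the ligand out in a rigidly displaced frame
    rot = _random_rotation(rng)
    shift = rng.uniform(-4.0, 4.0, size=3) + np.array([0.0, 0.0, 12.0])
    displaced = planted @ rot.T + shift
    ligand_input = ligand.with_coords(displaced)
    return ToySystem(receptor, ligand_input, planted, box, sampling, ranking,
                     anchors, seed, cfg)


def _random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _build_ligand(spec: ToySpec, anchors: list[PharmacophorePoint], rng
                  ) -> tuple[MolecularGraph, np.ndarray]:
    """Pseudo-ligand with features exactly on the anchor points.

    Polar anchors get an O-H (donor) or a bare O (acceptor); hydrophobic
    anchors get terminal carbons; a filler carbon ring near the pocket centre
    brings the heavy-atom count to >= 10 and carries the requested number of
    rotatable bonds.
    """
    donor_anchors = [a for a in anchors if a.type == FeatureType.DONOR]
    acceptor_anchors = [a for a in anchors if a.type == FeatureType.ACCEPTOR]
    hydro_anchors = [a for a in anchors if a.type == FeatureType.HYDROPHOBIC]
    centre = np.mean([a.position for a in anchors], axis=0)

    atoms: list[Atom] = []
    bonds: list[Bond] = []
    hub = len(donor_anchors) * 2 + len(acceptor_anchors)  # index of hub carbon C1

    for a in donor_anchors:
        h_idx = len(atoms)
        atoms.append(Atom("H", a.position))
        o_pos = a.position + 1.0 * _unit(centre - a.position)
        atoms.append(Atom("O", o_pos))
        bonds.append(Bond(h_idx, h_idx + 1))
        bonds.append(Bond(h_idx + 1, hub))
    for a in acceptor_anchors:
        o_idx = len(atoms)
        atoms.append(Atom("O", a.position))
        bonds.append(Bond(o_idx, hub))

    assert len(atoms) == hub
    atoms.append(Atom("C", centre + np.array([0.0, 0.0, 0.4])))  # hub C1
    for a in hydro_anchors:
        c_idx = len(atoms)
        atoms.append(Atom("C", a.position))
        bonds.append(Bond(c_idx, hub))

    # filler ring: lift until clear of the hydrophobic anchors
    ring_centre = centre + np.array([0.0, 0.3, 1.4])
    hpos = np.array([a.position for a in hydro_anchors]) if hydro_anchors else None
    for _ in range(40):
        if hpos is None or np.min(np.linalg.norm(hpos - ring_centre, axis=1)) >= 3.3:
            break
        ring_centre = ring_centre + np.array([0.0, 0.0, 0.3])
    n_fill = max(10 - (len(atoms) - len(donor_anchors)), spec.n_rotors + 3)
    fill_idx = []
    for m in range(n_fill):
        phi = 2.0 * math.pi * m / n_fill
        pos = ring_centre + 1.1 * np.array([math.cos(phi), math.sin(phi), 0.0])
        fill_idx.append(len(atoms))
        atoms.append(Atom("C", pos))

    # chain bonds (rotatable) then a closed ring on the remaining fillers
    chain = [hub] + fill_idx[:spec.n_rotors]
    for a, b in itertools.pairwise(chain):
        bonds.append(Bond(a, b))
    ring = fill_idx[spec.n_rotors:]
    if len(ring) >= 3:
        for a, b in itertools.pairwise(ring + [ring[0]]):
            bonds.append(Bond(a, b, in_ring=True))
        # fuse the chain end to the ring through two bonds (a genuine cycle),
        # so the attachment itself is not an extra rotor
        attach = chain[-1]
        bonds.append(Bond(attach, ring[0], in_ring=True))
        bonds.append(Bond(attach, ring[1], in_ring=True))
    planted = np.array([a.position for a in atoms])
    mol = MolecularGraph(atoms, bonds, name="toy-ligand")
    return mol, planted


def receptor_to_pdb(receptor: MolecularGraph) -> str:
    """Serialise a pseudo-atom pocket as PDB text (one XXX residue per atom)."""
    lines = []
    for i, a in enumerate(receptor.atoms, start=1):
        x, y, z = a.position
        name = (a.element + str(i))[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s} XXX A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_cliques(graph: CorrespondenceGraph, min_size: int = 3
                        ) -> list[tuple[int, ...]]:
    """Exhaustive maximal-clique enumeration; guard-railed to <= 14 nodes."""
    n = len(graph.nodes)
    if n > 14:
        raise ValueError("brute-force clique oracle limited to 14 nodes")
    adj = graph.adjacency
    all_cliques = []
    for size in range(min_size, n + 1):
        for subset in itertools.combinations(range(n), size):
            if all(adj[a, b] for a, b in itertools.combinations(subset, 2)):
                all_cliques.append(set(subset))
    maximal = [c for c in all_cliques
               if not any(c < other for other in all_cliques)]
    out = sorted({tuple(sorted(c)) for c in maximal})
    out.sort(key=lambda c: (-len(c), c))
    return out


def brute_force_pharm_score(features, model: PharmacophoreModel) -> float:
    """Naive nearest-neighbour pharmacophore score; oracle for pharm_score."""
    sums = {k: 0.0 for k in WEIGHTS}
    for feat in features:
        cls = _CLASS_OF.get(feat.type)
        if cls is None:
            continue
        best = None
        for p in model.points:
            if p.type != feat.type:
                continue
            r = float(np.linalg.norm(p.position - feat.position))
            if best is None or r < best:
                best = r
        if best is not None:
            sums[cls] += f_r(best)
    return -sum(WEIGHTS[k] * v for k, v in sums.items())


# Hand-built synthetic serine-like fragment (plus one cofactor carbon) used to
# exercise the PDB reader; not derived from any experimental structure.
MINI_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  OG  SER A   1       3.430   1.400   0.100  1.00  0.00           O
ATOM      5  HG  SER A   1       3.750   2.280   0.250  1.00  0.00           H
ATOM      6  C   SER A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      7  O   SER A   1       1.350  -1.800  -1.500  1.00  0.00           O
HETATM    8  C1  LIG A 101       6.000   4.000   3.000  1.00  0.00           C
END
"""
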