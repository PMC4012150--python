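"""Piecewise-linear pairwise (PLP) scoring and Metropolis Monte Carlo refinement.

The PLP energy is a sum over ligand-heavy x receptor-heavy atom pairs. Each
pair is either a hydrogen-bond pair (one side can donate, the other accept)
or a steric pair, and contributes a piecewise-linear potential: repulsive
below A (reaching F at r = 0), descending to the well depth E between A and
B, flat until C, back to zero at D, and zero beyond. Parameter defaults
follow the original PLP parameterisation: HBOND (2.3, 2.6, 3.1, 3.4) A with
well depth -2.0, STERIC (3.4, 3.6, 4.5, 5.5) A with well depth -0.4,
repulsion cap 20 for both.

Each top-ranked pose is refined by a local Metropolis Monte Carlo search:
random rigid-body and torsion perturbations, acceptance by the Metropolis
criterion at RT = 1.986 cal/(mol K) x 300 K, a hard 3.5 A in-place RMSD leash
to the start pose, step sizes adapted to keep the acceptance rate between 0.4
and 0.6 over 100-step windows, a reset to the start pose after three
consecutive rejections, and torsion steps damped for bulky branches by

    ratio = (1 + cos(pi * N_atoms / N_max)) * 0.5 * (1 - eps) + eps   (N_atoms < N_max)
    ratio = eps                                                       (N_atoms >= N_max)

with eps = 0.15 and N_max = 8. The best pose seen along the trajectory is
returned, so refinement can never worsen a pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_chem import (MolecularGraph, PLPAtomClass, assign_plp_class,
                        classify_pair_interaction, count_rotatable_bonds)
from .pose_sampler import Pose

__all__ = [
    "PLPPiece",
    "PLPParams",
    "DEFAULT_PLP",
    "MCConfig",
    "MCState",
    "ReceptorPLP",
    "plp_pair_energy",
    "plp_total",
    "torsion_scale",
    "metropolis_decide",
    "adapt_step_sizes",
    "propose_move",
    "mc_optimize",
    "ligand_torsions",
]

GAS_CONSTANT = 1.986  # cal / (mol K)


@dataclass(frozen=True)
class PLPPiece:
    """Knots and depths of one piecewise-linear pair potential."""

    A: float
    B: float
    C: float
    D: float
    E: float  # well depth (< 0)
    F: float  # repulsion at r = 0 (> 0)

    def __post_init__(self):
        if not (0 < self.A < self.B < self.C < self.D):
            raise ValueError("PLP knots must satisfy 0 < A < B < C < D")
        if self.E >= 0 or self.F <= 0:
            raise ValueError("PLP well depth must be negative and repulsion cap positive")


@dataclass(frozen=True)
class PLPParams:
    hbond: PLPPiece = field(default_factory=lambda: PLPPiece(2.3, 2.6, 3.1, 3.4, -2.0, 20.0))
    steric: PLPPiece = field(default_factory=lambda: PLPPiece(3.4, 3.6, 4.5, 5.5, -0.4, 20.0))

    def piece(self, label: str) -> PLPPiece:
        return self.hbond if label == "HBOND" else self.steric


DEFAULT_PLP = PLPParams()


def plp_pair_energy(r, label: str, params: PLPParams = DEFAULT_PLP):
    """Energy of one atom pair at distance r for an HBOND or STERIC pair."""
    p = params.piece(label)
    r = np.asarray(r, dtype=float)
    out = np.interp(r, [0.0, p.A, p.B, p.C, p.D], [p.F, 0.0, p.E, p.E, 0.0],
                    right=0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ReceptorPLP:
    """Precomputed receptor-side data for fast repeated PLP evaluation."""

    coords: np.ndarray                 # heavy-atom coordinates
    classes: list[PLPAtomClass]

    @classmethod
    def from_graph(cls, receptor: MolecularGraph) -> "ReceptorPLP":
        heavy = receptor.heavy_indices()
        return cls(receptor.coords[heavy], [assign_plp_class(i, receptor) for i in heavy])


def _pair_label_matrix(lig_classes, rec_classes) -> np.ndarray:
    hb = np.zeros((len(lig_classes), len(rec_classes)), dtype=bool)
    for i, a in enumerate(lig_classes):
        for j, b in enumerate(rec_classes):
            hb[i, j] = classify_pair_interaction(a, b) == "HBOND"
    return hb


def plp_total(lig_coords: np.ndarray, lig_classes, receptor: ReceptorPLP,
              params: PLPParams = DEFAULT_PLP, hbond_mask: np.ndarray | None = None) -> float:
    """Total PLP energy of a placed ligand against the receptor.

    Receptor atoms beyond the potential support of every ligand atom
    contribute exactly zero and are skipped.
    """
    lig = np.asarray(lig_coords, float)
    if len(lig) == 0 or len(receptor.coords) == 0:
        return 0.0
    if hbond_mask is None:
        hbond_mask = _pair_label_matrix(lig_classes, receptor.classes)
    d_max = max(params.hbond.D, params.steric.D)
    centroid = lig.mean(axis=0)
    diameter = float(np.max(np.linalg.norm(lig - centroid, axis=1)))
    near = np.linalg.norm(receptor.coords - centroid, axis=1) <= d_max + diameter
    if not np.any(near):
        return 0.0
    d = np.linalg.norm(lig[:, None] - receptor.coords[near][None, :], axis=2)
    hb = hbond_mask[:, near]
    e_h = plp_pair_energy(d[hb], "HBOND", params).sum() if np.any(hb) else 0.0
    e_s = plp_pair_energy(d[~hb], "STERIC", params).sum() if np.any(~hb) else 0.0
    return float(e_h + e_s)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class MCConfig:
    n_steps: int = 1000
    rmsd_cap: float = 3.5          # A, leash to the start pose (in place)
    temperature: float = 300.0     # K
    gas_constant: float = GAS_CONSTANT
    window: int = 100              # steps per acceptance-rate window
    rate_low: float = 0.4
    rate_high: float = 0.6
    eps: float = 0.15              # torsion damping floor
    n_max: int = 8                 # branch size at which damping saturates
    step_translation: float = 0.5  # A
    step_rotation: float = 15.0    # degrees
    step_torsion: float = 60.0     # degrees
    shrink: float = 0.9
    grow: float = 1.1
    clamp_low: float = 0.05        # x base step size
    clamp_high: float = 4.0        # x base step size
    max_consecutive_rejects: int = 3
    energy_scale: float = 1000.0   # cal/mol per PLP energy unit
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.rate_low < self.rate_high):
            raise ValueError("need 0 < rate_low < rate_high")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class StepSizes:
    translation: float
    rotation: float
    torsion: float

    def scaled(self, factor: float, cfg: MCConfig) -> "StepSizes":
        def clamp(v, base):
            return float(np.clip(v * factor, cfg.clamp_low * base, cfg.clamp_high * base))
        return StepSizes(clamp(self.translation, cfg.step_translation),
                         clamp(self.rotation, cfg.step_rotation),
                         clamp(self.torsion, cfg.step_torsion))


@dataclass
class Torsion:
    axis_i: int          # atom on the fixed side
    axis_j: int          # atom on the rotating side
    branch: list[int]    # atom indices rotated with the bond (smaller side)
    n_heavy_branch: int  # heavy atoms on the smaller side


@dataclass
class MCState:
    start_coords: np.ndarray
    current_coords: np.ndarray
    best_coords: np.ndarray
    score_cur: float
    score_pre: float
    score_min: float
    sizes: StepSizes
    history: list[bool] = field(default_factory=list)
    consecutive_rejects: int = 0


def torsion_scale(n_atoms: int, eps: float = 0.15, n_max: int = 8) -> float:
    """Damping ratio for the maximum torsion step, by smaller-branch size."""
    if n_atoms <= 0:
        raise ValueError("branch heavy-atom count must be positive")
    if n_atoms >= n_max:
        return float(eps)
    return float((1.0 + math.cos(math.pi * n_atoms / n_max)) * 0.5 * (1.0 - eps) + eps)


def ligand_torsions(mol: MolecularGraph) -> list[Torsion]:
    """Rotatable torsions with smaller-branch atom sets precomputed."""
    import networkx as nx

    heavy = set(mol.heavy_indices())
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    for b in mol.bonds:
        g.add_edge(b.i, b.j)
    torsions = []
    for b in mol.bonds:
        if b.in_ring or b.aromatic or b.order != 1.0:
            continue
        if b.i not in heavy or b.j not in heavy:
            continue
        ni = [k for k in mol.neighbors(b.i) if k != b.j and k in heavy]
        nj = [k for k in mol.neighbors(b.j) if k != b.i and k in heavy]
        if not ni or not nj:
            continue
        h = g.copy()
        h.remove_edge(b.i, b.j)
        side_j = nx.node_connected_component(h, b.j)
        side_i = nx.node_connected_component(h, b.i)
        if side_i == side_j:  # bond closes a ring not flagged as such
            continue
        heavy_j = len((side_j - {b.j}) & heavy)
        heavy_i = len((side_i - {b.i}) & heavy)
        if heavy_j <= heavy_i:
            branch, n_h, ai, aj = sorted(side_j - {b.j}), heavy_j, b.i, b.j
        else:
            branch, n_h, ai, aj = sorted(side_i - {b.i}), heavy_i, b.j, b.i
        if n_h == 0:
            continue
        torsions.append(Torsion(ai, aj, branch, n_h))
    return torsions


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def propose_move(coords: np.ndarray, torsions: list[Torsion], sizes: StepSizes,
                 rng: np.random.Generator, config: MCConfig) -> np.ndarray:
    """Random perturbation of position, orientation and torsion angles."""
    out = np.asarray(coords, float).copy()
    # torsions first (internal), then rigid-body motion
    for t in torsions:
        scale = torsion_scale(t.n_heavy_branch, config.eps, config.n_max)
        ang = rng.uniform(-1.0, 1.0) * math.radians(sizes.torsion * scale)
        axis = out[t.axis_j] - out[t.axis_i]
        if np.linalg.norm(axis) < 1e-9:
            continue
        rot = _rotation_matrix(axis, ang)
        pivot = out[t.axis_j]
        out[t.branch] = (out[t.branch] - pivot) @ rot.T + pivot
    # rigid rotation about the centroid
    axis = rng.normal(size=3)
    while np.linalg.norm(axis) < 1e-9:
        axis = rng.normal(size=3)
    ang = rng.uniform(-1.0, 1.0) * math.radians(sizes.rotation)
    if ang != 0.0:
        rot = _rotation_matrix(axis, ang)
        centroid = out.mean(axis=0)
        out = (out - centroid) @ rot.T + centroid
    # translation
    out = out + rng.uniform(-1.0, 1.0, size=3) * sizes.translation
    return out


def metropolis_decide(score_cur: float, score_min: float, score_pre: float,
                      rmsd_from_start: float, config: MCConfig,
                      rng: np.random.Generator) -> str:
    """ACCEPT / REJECT / RESET for one proposed pose.

    A pose straying more than the RMSD cap from the start pose forces a RESET;
    a new global minimum is always accepted; otherwise the Metropolis factor
    exp(-(cur - pre) / RT) must exceed a uniform draw (strict inequality).
    """
    if rmsd_from_start > config.rmsd_cap:
        return "RESET"
    if score_cur < score_min:
        return "ACCEPT"
    p = math.exp(-(score_cur - score_pre) * config.energy_scale / config.rt)
    return "ACCEPT" if p > rng.uniform(0.0, 1.0) else "REJECT"


def adapt_step_sizes(history: list[bool], sizes: StepSizes, config: MCConfig) -> StepSizes:
    """Shrink or grow all step sizes from the last-window acceptance rate."""
    if len(history) < config.window:
        return sizes
    rate = sum(history[-config.window:]) / config.window
    if rate < config.rate_low:
        return sizes.scaled(config.shrink, config)
    if rate > config.rate_high:
        return sizes.scaled(config.grow, config)
    return sizes


def mc_optimize(pose: Pose, mol: MolecularGraph, receptor: ReceptorPLP,
                params: PLPParams = DEFAULT_PLP, config: MCConfig | None = None,
                trace: list | None = None) -> Pose:
    """Metropolis Monte Carlo refinement of one pose; returns the best pose seen."""
    cfg = config or MCConfig()
    rng = np.random.default_rng(cfg.seed)
    heavy = mol.heavy_indices()
    lig_classes = [assign_plp_class(i, mol) for i in heavy]
    hbond_mask = _pair_label_matrix(lig_classes, receptor.classes)
    torsions = ligand_torsions(mol)

    def energy(coords):
        return plp_total(coords[heavy], lig_classes, receptor, params, hbond_mask)

    e0 = energy(pose.coordinates)
    if cfg.n_steps <= 0:
        return replace_pose(pose, pose.coordinates, e0)

    st = MCState(pose.coordinates.copy(), pose.coordinates.copy(),
                 pose.coordinates.copy(), e0, e0, e0,
                 StepSizes(cfg.step_translation, cfg.step_rotation, cfg.step_torsion))
    start_heavy = st.start_coords[heavy]
    for step in range(cfg.n_steps):
        cand = propose_move(st.current_coords, torsions, st.sizes, rng, cfg)
        r = float(np.sqrt(np.mean(np.sum((cand[heavy] - start_heavy) ** 2, axis=1))))
        e_cand = energy(cand)
        decision = metropolis_decide(e_cand, st.score_min, st.score_pre, r, cfg, rng)
        if decision == "ACCEPT":
            st.current_coords = cand
            st.score_cur = e_cand
            st.score_pre = e_cand
            st.consecutive_rejects = 0
            if e_cand < st.score_min:
                st.score_min = e_cand
                st.best_coords = cand.copy()
            st.history.append(True)
        else:
            st.consecutive_rejects += 1
            st.history.append(False)
            if decision == "RESET" or st.consecutive_rejects >= cfg.max_consecutive_rejects:
                st.current_coords = st.start_coords.copy()
                st.score_cur = e0
                st.score_pre = e0
                st.consecutive_rejects = 0
        if (step + 1) % cfg.window == 0:
            st.sizes = adapt_step_sizes(st.history, st.sizes, cfg)
        if trace is not None:
            r_now = float(np.sqrt(np.mean(np.sum(
                (st.current_coords[heavy] - start_heavy) ** 2, axis=1))))
            trace.append((step, st.score_cur, st.score_min, decision, r_now,
                          st.sizes.translation, st.sizes.rotation, st.sizes.torsion))
    return replace_pose(pose, st.best_coords, st.score_min)


def replace_pose(pose: Pose, coords: np.ndarray, energy: float) -> Pose:
    return Pose(pose.conformer_index, np.asarray(coords, float), pose.clique,
                pose.pharm_score, float(energy), pose.pose_index, pose.breakdown)
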