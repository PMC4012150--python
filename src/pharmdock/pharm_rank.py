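"""Pharmacophore match scoring and pose selection.

A placed pose is scored against the dense ranking model: every ligand feature
is paired with its closest protein-based point of the same type at distance r
and contributes f(r), where f is 1 below 0.5 A, falls linearly to 0 at 1.0 A,
and is 0 beyond. Class sums are combined as

    S = -0.7 * sum_hbond f - 0.4 * sum_hphob f - 0.6 * sum_arom f - 0.6 * sum_ionic f

with donors and acceptors pooled into the hydrogen-bond sum and both charge
signs into the ionic sum. More negative S is better; the top-N poses by S go
on to Monte Carlo refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_chem import FeatureType, PharmacophorePoint
from .ligand_conformers import conformer_features
from .pose_sampler import Pose
from .protein_pharm import PharmacophoreModel

__all__ = ["PharmScoreBreakdown", "f_r", "pharm_score", "score_poses",
           "rank_and_select", "WEIGHTS"]

# class weights: hydrogen bond, hydrophobic, aromatic, ionic
WEIGHTS = {"hbond": 0.7, "hphob": 0.4, "arom": 0.6, "ionic": 0.6}

_CLASS_OF = {
    FeatureType.DONOR: "hbond",
    FeatureType.ACCEPTOR: "hbond",
    FeatureType.HYDROPHOBIC: "hphob",
    FeatureType.AROMATIC: "arom",
    FeatureType.POSITIVE: "ionic",
    FeatureType.NEGATIVE: "ionic",
}


@dataclass
class PharmScoreBreakdown:
    S: float
    sums: dict = field(default_factory=dict)            # per-class sum of f(r)
    matched_pairs: list = field(default_factory=list)   # (feature idx, point idx, r)


def f_r(r):
    """Distance weight of a matched pharmacophore pair; support [0, 1] A."""
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pharmacophore pair distance must be non-negative")
    out = np.where(arr <= 0.5, 1.0, np.where(arr <= 1.0, 2.0 * (1.0 - arr), 0.0))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def pharm_score(features: list[PharmacophorePoint],
                ranking_model: PharmacophoreModel) -> PharmScoreBreakdown:
    """Score a placed feature set against the dense ranking model.

    All ligand features contribute, not only those of the matching clique;
    a protein point may serve several ligand features.
    """
    sums = {k: 0.0 for k in WEIGHTS}
    pairs = []
    if ranking_model.points:
        by_type: dict[FeatureType, tuple[np.ndarray, list[int]]] = {}
        for ftype in _CLASS_OF:
            idx = [i for i, p in enumerate(ranking_model.points) if p.type == ftype]
            if idx:
                by_type[ftype] = (np.array([ranking_model.points[i].position for i in idx]), idx)
        for fi, feat in enumerate(features):
            entry = by_type.get(feat.type)
            if entry is None:
                continue
            pos, idx = entry
            d = np.linalg.norm(pos - feat.position, axis=1)
            j = int(np.argmin(d))
            r = float(d[j])
            w = f_r(r)
            if w > 0:
                sums[_CLASS_OF[feat.type]] += w
                pairs.append((fi, idx[j], r))
    s = -sum(WEIGHTS[k] * v for k, v in sums.items())
    return PharmScoreBreakdown(s, sums, pairs)


def score_poses(poses: list[Pose], mol, ranking_model: PharmacophoreModel) -> None:
    """Attach S (and its breakdown) to each pose in place."""
    for pose in poses:
        feats = conformer_features(mol, pose.coordinates)
        bd = pharm_score(feats, ranking_model)
        pose.pharm_score = bd.S
        pose.breakdown = bd


def rank_and_select(poses: list[Pose], n: int = 100) -> list[Pose]:
    """Top-n poses by ascending S with a deterministic tie-break."""
    if any(p.pharm_score is None for p in poses):
        raise ValueError("all poses must be scored before ranking")
    ordered = sorted(poses, key=lambda p: (p.pharm_score, -len(p.clique),
                                           p.conformer_index, p.pose_index))
    return ordered[:n]


def breakdown_table(poses: list[Pose]) -> str:
    """Tab-separated score table (pose id, S, class sums, matched pairs)."""
    lines = ["pose\tS\thbond\thphob\tarom\tionic\tn_matched"]
    for p in poses:
        bd = p.breakdown
        sums = bd.sums if bd else {k: 0.0 for k in WEIGHTS}
        nm = len(bd.matched_pairs) if bd else 0
        s = p.pharm_score if p.pharm_score is not None else float("nan")
        lines.append(f"{p.pose_index}\t{s:.4f}\t" +
                     "\t".join(f"{sums[k]:.4f}" for k in ("hbond", "hphob", "arom", "ionic")) +
                     f"\t{nm}")
    return "\n".join(lines) + "\n"
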