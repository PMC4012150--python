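"""End-to-end docking pipeline: model building, sampling, ranking, refinement.

The unbiased pipeline is: build the two protein pharmacophore models ->
clique-match each conformer against the sampling model -> place and
clash-filter -> score every surviving pose against the ranking model ->
select the top-N by pharmacophore score -> Metropolis Monte Carlo refinement
of each under the PLP potential -> final ranking by PLP energy.

Two biased modes restrict the search with a user selection of protein
pharmacophores: *confined* docking replaces both models by the selected
subset (forbidden points are always kept, clash testing is never relaxed);
*constraint* docking samples the full site but discards poses that match
none of the selected points within the 1 A support of the scoring function.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_chem import FeatureType, MolecularGraph, PharmacophorePoint
from .ligand_conformers import ConformerEnsemble, ensembles_from_file
from .pharm_rank import breakdown_table, rank_and_select, score_poses
from .plp_mc import DEFAULT_PLP, MCConfig, PLPParams, ReceptorPLP, mc_optimize
from .pose_sampler import Pose, sample_poses
from .protein_pharm import (BindingSiteBox, PharmacophoreModel, PharmGenConfig,
                            build_models, define_binding_site, write_model)
from . import io as pdio

__all__ = ["DockingConfig", "LigandResult", "DockingResult", "dock",
           "select_pharmacophores", "apply_confined_mode",
           "apply_constraint_filter", "write_results"]

log = logging.getLogger(__name__)

CONSTRAINT_MATCH_RADIUS = 1.0  # A; the support of the pharmacophore weight f(r)


@dataclass
class DockingConfig:
    receptor: MolecularGraph | str
    ligands: list[ConformerEnsemble] | str
    box: BindingSiteBox | None = None
    reference_ligand: MolecularGraph | str | None = None
    mode: str = "unbiased"                   # unbiased | confined | constraint
    selection: list[PharmacophorePoint] | None = None
    selection_snap_radius: float = 0.75      # A, matching selection entries to model points
    top_n_mc: int = 100
    output_n: int = 10
    seed: int = 0
    max_confs: int = 100
    energy_window: float = 15.0
    pharm_config: PharmGenConfig = field(default_factory=PharmGenConfig)
    mc_config: MCConfig = field(default_factory=MCConfig)
    plp_params: PLPParams = field(default_factory=lambda: DEFAULT_PLP)
    models: tuple[PharmacophoreModel, PharmacophoreModel] | None = None

    def __post_init__(self):
        if self.mode not in ("unbiased", "confined", "constraint"):
            raise ValueError(f"unknown docking mode {self.mode!r}")
        if self.mode != "unbiased" and not self.selection:
            raise ValueError(f"{self.mode} docking requires a non-empty pharmacophore selection")


@dataclass
class LigandResult:
    name: str
    poses: list[Pose]                 # ascending PLP energy
    n_sampled: int
    n_after_constraint: int
    warning: str = ""

    @property
    def best_plp(self) -> float:
        return self.poses[0].plp_energy if self.poses else float("inf")


@dataclass
class DockingResult:
    ligands: list[LigandResult]
    sampling_model: PharmacophoreModel
    ranking_model: PharmacophoreModel
    config: DockingConfig

    def ranking_table(self) -> str:
        """Library-level TSV, ascending best PLP energy."""
        rows = sorted(self.ligands, key=lambda r: (r.best_plp, r.name))
        lines = ["ligand\tbest_plp_energy\tbest_pharm_score\tn_poses\tn_sampled"]
        for r in rows:
            s = f"{r.poses[0].pharm_score:.4f}" if r.poses else ""
            e = f"{r.best_plp:.4f}" if r.poses else ""
            lines.append(f"{r.name}\t{e}\t{s}\t{len(r.poses)}\t{r.n_sampled}")
        return "\n".join(lines) + "\n"


def select_pharmacophores(model: PharmacophoreModel,
                          ids: list[int] | None = None,
                          points: list[PharmacophorePoint] | None = None,
                          predicate=None,
                          snap_radius: float = 0.75) -> PharmacophoreModel:
    """Subset a model by point ids, by typed reference positions, or by a
    predicate on points; the forbidden set is always retained in full."""
    if ids is not None:
        return model.subset(ids)
    keep = []
    for i, p in enumerate(model.points):
        if predicate is not None and predicate(p):
            keep.append(i)
        elif points is not None and any(
                s.type == p.type and np.linalg.norm(s.position - p.position) <= snap_radius
                for s in points):
            keep.append(i)
    return model.subset(keep)


def apply_confined_mode(models, selection, snap_radius: float = 0.75):
    """Replace sampling and ranking models by the selected subsets."""
    sampling, ranking = models
    return (select_pharmacophores(sampling, points=selection, snap_radius=snap_radius),
            select_pharmacophores(ranking, points=selection, snap_radius=snap_radius))


def apply_constraint_filter(poses: list[Pose], ranking_model: PharmacophoreModel,
                            selection, snap_radius: float = 0.75,
                            match_radius: float = CONSTRAINT_MATCH_RADIUS) -> list[Pose]:
    """Keep poses with at least one ligand feature matching a selected point.

    Poses must already be scored against the full ranking model: the recorded
    matched pairs (all within the f(r) support) are tested against the
    selected point set. Surviving poses are untouched.
    """
    selected_ids = {
        i for i, p in enumerate(ranking_model.points)
        if any(s.type == p.type and np.linalg.norm(s.position - p.position) <= snap_radius
               for s in selection)
    }
    out = []
    for pose in poses:
        pairs = pose.breakdown.matched_pairs if pose.breakdown else []
        if any(j in selected_ids and r <= match_radius for _, j, r in pairs):
            out.append(pose)
    return out


def _ligand_seed(base: int, index: int) -> int:
    return (base * 100_003 + 7919 * index + 1) % (2**31)


def dock(config: DockingConfig) -> DockingResult:
    """Run the full docking pipeline for a ligand library."""
    receptor = (pdio.load_receptor_pdb(config.receptor)
                if isinstance(config.receptor, (str, Path)) else config.receptor)
    if config.box is not None:
        box = config.box
    elif config.reference_ligand is not None:
        ref = config.reference_ligand
        if isinstance(ref, (str, Path)):
            from .io import load_ligands, graph_from_rdkit

            ref = graph_from_rdkit(load_ligands(ref)[0][0])
        box = define_binding_site(receptor, ref)
    else:
        raise ValueError("a binding-site box or reference ligand is required")

    if config.models is not None:
        sampling, ranking = config.models
    else:
        sampling, ranking = build_models(receptor, box, config.pharm_config)
    if config.mode == "confined":
        sampling, ranking = apply_confined_mode((sampling, ranking), config.selection,
                                                config.selection_snap_radius)

    if isinstance(config.ligands, (str, Path)):
        ensembles = ensembles_from_file(config.ligands, config.max_confs,
                                        config.energy_window)
    else:
        ensembles = list(config.ligands)
    if not ensembles:
        log.warning("empty ligand library: nothing to dock")

    receptor_plp = ReceptorPLP.from_graph(receptor)
    results: list[LigandResult] = []
    for li, ens in enumerate(ensembles):
        name = ens.mol.name or f"ligand_{li}"
        try:
            poses = sample_poses(ens, sampling)
            n_sampled = len(poses)
            score_poses(poses, ens.mol, ranking)
            if config.mode == "constraint":
                poses = apply_constraint_filter(poses, ranking, config.selection,
                                                config.selection_snap_radius)
            n_after = len(poses)
            top = rank_and_select(poses, config.top_n_mc)
            lig_seed = _ligand_seed(config.seed, li)
            refined = []
            for pi, pose in enumerate(top):
                mc = MCConfig(**{**config.mc_config.__dict__,
                                 "seed": (lig_seed + 65_537 * pi) % (2**31)})
                refined.append(mc_optimize(pose, ens.mol, receptor_plp,
                                           config.plp_params, mc))
            refined.sort(key=lambda p: (p.plp_energy,
                                        p.pharm_score if p.pharm_score is not None else 0.0,
                                        p.pose_index))
            warn = "" if refined else "no surviving poses"
            results.append(LigandResult(name, refined[:config.output_n],
                                        n_sampled, n_after, warn))
            if warn:
                log.warning("%s: %s", name, warn)
        except ValueError as exc:
            log.warning("ligand %s failed: %s", name, exc)
            results.append(LigandResult(name, [], 0, 0, str(exc)))
    return DockingResult(results, sampling, ranking, config)


def write_results(result: DockingResult, out_dir: str | Path) -> list[Path]:
    """Write per-ligand pose SDFs, the library ranking TSV, pharmacophore
    model files, and a machine-readable run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ens_by_name = {}
    if not isinstance(result.config.ligands, (str, Path)):
        for li, ens in enumerate(result.config.ligands):
            ens_by_name[ens.mol.name or f"ligand_{li}"] = ens
    else:
        for li, ens in enumerate(ensembles_from_file(result.config.ligands,
                                                     result.config.max_confs,
                                                     result.config.energy_window)):
            ens_by_name[ens.mol.name or f"ligand_{li}"] = ens

    for lig in result.ligands:
        if not lig.poses or lig.name not in ens_by_name:
            continue
        path = out / f"{lig.name}_poses.sdf"
        pdio.write_poses_sdf(path, ens_by_name[lig.name].mol, lig.poses)
        written.append(path)
        score_path = out / f"{lig.name}_scores.tsv"
        score_path.write_text(breakdown_table(lig.poses))
        written.append(score_path)

    table = out / "ranking.tsv"
    table.write_text(result.ranking_table())
    written.append(table)
    for label, model in (("sampling", result.sampling_model),
                         ("ranking", result.ranking_model)):
        p = out / f"pharmacophores_{label}.txt"
        write_model(model, p)
        written.append(p)

    from . import __version__

    cfg = result.config
    manifest = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "top_n_mc": cfg.top_n_mc,
        "output_n": cfg.output_n,
        "max_confs": cfg.max_confs,
        "energy_window": cfg.energy_window,
        "mc": {k: v for k, v in cfg.mc_config.__dict__.items()},
        "ligands": [lig.name for lig in result.ligands],
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written.append(mpath)
    return written
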