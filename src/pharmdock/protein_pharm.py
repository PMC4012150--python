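"""Protein-based pharmacophore model generation.

A 3D grid is laid over the binding site and, per probe type, a smooth
block-function interaction field is computed against the complementary protein
groups (acceptors for a donor probe, donor hydrogens for an acceptor probe,
apolar atoms for a hydrophobic probe, ring centres and charged groups for the
aromatic and ionic probes). Favorable grid points are condensed into
pharmacophore points by adaptive k-means clustering: for the hydrophobic field
over the whole favorable cloud, for directional fields within per-group
patches. Protein-occupied volume is exported as forbidden points used by the
steric clash filter.

Two model densities are produced: a sparse *sampling* model (hydrophobic at
1.5 A, hydrogen-bond points at 2.0 A) used for clique matching, and a dense
*ranking* model (all types at 1.0 A) used for pose scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core_chem import FeatureType, MolecularGraph, PharmacophorePoint

__all__ = [
    "BindingSiteBox",
    "GridField",
    "PharmacophoreModel",
    "PharmGenConfig",
    "define_binding_site",
    "score_grid",
    "cluster_hydrophobic_field",
    "cluster_directional_field",
    "build_forbidden",
    "build_models",
    "write_model",
    "read_model",
]

_DIRECTIONAL = (FeatureType.DONOR, FeatureType.ACCEPTOR, FeatureType.AROMATIC,
                FeatureType.POSITIVE, FeatureType.NEGATIVE)


@dataclass
class BindingSiteBox:
    min_corner: np.ndarray
    max_corner: np.ndarray
    provenance: str = "user_box"

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, float)
        self.max_corner = np.asarray(self.max_corner, float)
        if not np.all(self.max_corner > self.min_corner):
            raise ValueError("binding-site box must have max_corner > min_corner")


@dataclass
class GridField:
    spacing: float
    origin: np.ndarray
    dims: tuple[int, int, int]
    values: np.ndarray  # flat, one scalar per grid point, <= 0
    probe: FeatureType

    def grid_coords(self) -> np.ndarray:
        nx, ny, nz = self.dims
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return self.origin + idx * self.spacing


@dataclass
class PharmacophoreModel:
    points: list[PharmacophorePoint]
    forbidden: np.ndarray  # (m, 3)
    density_label: str = "sampling"
    cutoffs: dict = field(default_factory=dict)

    def by_type(self, ftype: FeatureType) -> list[PharmacophorePoint]:
        return [p for p in self.points if p.type == ftype]

    def positions(self, ftype: FeatureType) -> np.ndarray:
        pts = self.by_type(ftype)
        return np.array([p.position for p in pts]) if pts else np.empty((0, 3))

    def subset(self, indices) -> "PharmacophoreModel":
        """Restricted model keeping the forbidden set in full."""
        idx = sorted(set(indices))
        bad = [i for i in idx if not 0 <= i < len(self.points)]
        if bad:
            raise KeyError(f"unknown pharmacophore ids {bad}; valid ids are 0..{len(self.points) - 1}")
        return PharmacophoreModel([self.points[i] for i in idx], self.forbidden,
                                  self.density_label, dict(self.cutoffs))


@dataclass
class PharmGenConfig:
    """Parameters of the grid potentials and clustering.

    Block functions B(x; x1, x2) are 1 for x <= x1 and decay linearly to 0 at
    x2. Hydrogen bonds use an ideal probe-to-group distance of 1.85 A with a
    (0.25, 0.65) A distance block and a (30, 80) degree angular block about
    the ideal linear geometry; the hydrophobic term uses the sum of van der
    Waals radii as ideal contact distance with a (0.5, 3.0) A block; aromatic
    and ionic terms reuse the hydrogen-bond block widths at ideal distances of
    3.7 and 2.8 A.
    """

    spacing: float = 0.4
    hb_ideal: float = 1.85
    hb_dist_block: tuple[float, float] = (0.25, 0.65)
    hb_ang_block: tuple[float, float] = (30.0, 80.0)
    hydrophobic_block: tuple[float, float] = (0.5, 3.0)
    probe_vdw: float = 1.70
    aromatic_ideal: float = 3.7
    ionic_ideal: float = 2.8
    weight: float = 1.0
    sampling_cutoff_hydrophobic: float = 1.5
    sampling_cutoff_hbond: float = 2.0
    ranking_cutoff: float = 1.0
    forbidden_spacing: float = 0.8
    # extra clearance (A) beyond the protein vdW radius for heavy-atom probes;
    # a ligand heavy atom cannot sit at the vdW surface itself, whereas the
    # donor probe is a hydrogen and only the bare vdW volume is excluded
    clearance_heavy_extra: float = 1.0
    max_clusters: int = 60
    kmeans_seed: int = 7
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-4


def _block(x: np.ndarray, x1: float, x2: float) -> np.ndarray:
    """ChemScore-style block: 1 below x1, linear to 0 at x2."""
    x = np.asarray(x, float)
    out = np.clip((x2 - x) / (x2 - x1), 0.0, 1.0)
    return out


def define_binding_site(receptor: MolecularGraph,
                        reference: MolecularGraph | BindingSiteBox) -> BindingSiteBox:
    """Axis-aligned box from a reference ligand (heavy-atom bbox + 3 A) or verbatim."""
    if isinstance(reference, BindingSiteBox):
        return reference
    heavy = reference.heavy_coords()
    if heavy.size == 0:
        raise ValueError("reference ligand has no heavy atoms")
    return BindingSiteBox(heavy.min(axis=0) - 3.0, heavy.max(axis=0) + 3.0,
                          provenance="reference_ligand")


# ---------------------------------------------------------------------------
# protein interaction sites
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    position: np.ndarray
    direction: np.ndarray | None  # unit vector toward the ideal partner, or None
    radius: float = 1.70


def protein_sites(receptor: MolecularGraph, probe: FeatureType) -> list[_Site]:
    """Complementary protein groups for a probe field.

    DONOR probe -> protein acceptors (with lone-pair direction from the bonded
    heavy-atom anchor); ACCEPTOR probe -> protein donor hydrogens (direction
    along the X-H bond); HYDROPHOBIC -> apolar heavy atoms; AROMATIC -> ring
    centres; POSITIVE/NEGATIVE -> oppositely charged protein atoms. Cofactor
    (HETATM) atoms are steric obstacles only and contribute no sites.
    """
    coords = receptor.coords
    sites: list[_Site] = []

    def anchor_dir(i: int) -> np.ndarray | None:
        heavies = [j for j in receptor.neighbors(i) if receptor.atoms[j].element != "H"]
        if not heavies:
            return None
        v = coords[i] - coords[heavies].mean(axis=0)
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else None

    if probe == FeatureType.DONOR:
        for i, a in enumerate(receptor.atoms):
            if a.hetero or a.element == "H":
                continue
            if receptor.is_acceptor_atom(i):
                sites.append(_Site(coords[i], anchor_dir(i)))
    elif probe == FeatureType.ACCEPTOR:
        for i, a in enumerate(receptor.atoms):
            if a.hetero or not (a.element == "H" and a.is_polar_hydrogen):
                continue
            roots = receptor.neighbors(i)
            d = None
            if roots:
                v = coords[i] - coords[roots[0]]
                n = np.linalg.norm(v)
                d = v / n if n > 1e-9 else None
            sites.append(_Site(coords[i], d))
    elif probe == FeatureType.HYDROPHOBIC:
        polar = {i for i in receptor.heavy_indices()
                 if receptor.is_acceptor_atom(i) or receptor.is_donor_heavy_atom(i)}
        for i, a in enumerate(receptor.atoms):
            if a.hetero or a.element == "H" or i in polar:
                continue
            if any(j in polar for j in receptor.neighbors(i)):
                continue
            sites.append(_Site(coords[i], None, radius=a.vdw_radius))
    elif probe == FeatureType.AROMATIC:
        for ring in receptor.aromatic_rings():
            if any(receptor.atoms[i].hetero for i in ring):
                continue
            sites.append(_Site(coords[ring].mean(axis=0), None))
    elif probe in (FeatureType.POSITIVE, FeatureType.NEGATIVE):
        want = -1 if probe == FeatureType.POSITIVE else 1
        for i, a in enumerate(receptor.atoms):
            if a.hetero or a.element == "H":
                continue
            if np.sign(a.formal_charge) == want:
                sites.append(_Site(coords[i], None))
    else:
        raise ValueError(f"no site definition for probe {probe}")
    return sites


# ---------------------------------------------------------------------------
# grid fields
# ---------------------------------------------------------------------------

def _make_grid(box: BindingSiteBox, spacing: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    span = box.max_corner - box.min_corner
    dims = tuple(int(math.floor(s / spacing)) + 1 for s in span)
    if min(dims) < 1:
        raise ValueError("binding-site box contains no grid points")
    return box.min_corner.copy(), dims  # origin at min corner


def score_grid(receptor: MolecularGraph, box: BindingSiteBox, probe: FeatureType,
               spacing: float | None = None,
               config: PharmGenConfig | None = None) -> GridField:
    """Interaction field of a probe over the binding-site grid (favorable < 0)."""
    cfg = config or PharmGenConfig()
    sp = cfg.spacing if spacing is None else spacing
    origin, dims = _make_grid(box, sp)
    field = GridField(sp, origin, dims, np.zeros(int(np.prod(dims))), probe)
    g = field.grid_coords()
    total = np.zeros(len(g))

    sites = protein_sites(receptor, probe)
    x1d, x2d = cfg.hb_dist_block
    a1, a2 = cfg.hb_ang_block
    for s in sites:
        dv = g - s.position
        r = np.linalg.norm(dv, axis=1)
        if probe in (FeatureType.DONOR, FeatureType.ACCEPTOR):
            val = _block(np.abs(r - cfg.hb_ideal), x1d, x2d)
            if s.direction is not None:
                with np.errstate(invalid="ignore", divide="ignore"):
                    cosang = np.where(r > 1e-9, dv @ s.direction / np.maximum(r, 1e-9), 1.0)
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                val = val * _block(ang, a1, a2)
        elif probe == FeatureType.HYDROPHOBIC:
            # ideal contact distance = probe + site van der Waals radii
            r_ideal = cfg.probe_vdw + s.radius
            val = _block(r - r_ideal, *cfg.hydrophobic_block)
        elif probe == FeatureType.AROMATIC:
            val = _block(np.abs(r - cfg.aromatic_ideal), x1d, x2d)
        else:  # ionic
            val = _block(np.abs(r - cfg.ionic_ideal), x1d, x2d)
        total -= cfg.weight * val

    # clamp grid points inside the protein van der Waals volume to 0; for
    # heavy-atom probes the sterically infeasible contact shell is excluded too
    heavy = receptor.heavy_indices()
    if heavy and len(g):
        from scipy.spatial import cKDTree

        extra = 0.0 if probe == FeatureType.DONOR else cfg.clearance_heavy_extra
        coords = receptor.coords[heavy]
        radii = np.array([receptor.atoms[i].vdw_radius for i in heavy])
        tree = cKDTree(g)
        inside = np.zeros(len(g), dtype=bool)
        for rad in np.unique(radii):
            sel = coords[radii == rad]
            hits = tree.query_ball_point(sel, r=float(rad) + extra)
            for h in hits:
                inside[h] = True
        total[inside] = 0.0

    field.values = total
    return field


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _adaptive_kmeans(coords: np.ndarray, weights: np.ndarray, cutoff: float,
                     cfg: PharmGenConfig) -> list[tuple[np.ndarray, float]]:
    """Increase k from 1 until cluster centres are on average closer than
    ``cutoff`` to their nearest neighbour; returns energy-weighted centres."""
    from sklearn.cluster import KMeans
    from scipy.spatial.distance import pdist, squareform

    n = len(coords)
    if n == 0:
        return []
    if n == 1:
        return [(coords[0].copy(), float(weights[0]))]
    k_cap = min(n, cfg.max_clusters)
    best = None
    for k in range(1, k_cap + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    max_iter=cfg.kmeans_max_iter, tol=cfg.kmeans_tol,
                    random_state=cfg.kmeans_seed)
        labels = km.fit_predict(coords)
        centres = []
        for lab in range(k):
            mask = labels == lab
            if not np.any(mask):
                continue
            w = weights[mask]
            centres.append((np.average(coords[mask], axis=0, weights=w), float(w.sum())))
        best = centres
        if len(centres) >= 2:
            pos = np.array([c for c, _ in centres])
            dm = squareform(pdist(pos))
            np.fill_diagonal(dm, np.inf)
            if float(dm.min(axis=1).mean()) < cutoff:
                break
    return best


def cluster_hydrophobic_field(field: GridField, cutoff: float,
                              config: PharmGenConfig | None = None) -> list[PharmacophorePoint]:
    """Condense the favorable hydrophobic cloud into energy-weighted centres."""
    cfg = config or PharmGenConfig()
    g = field.grid_coords()
    fav = field.values < 0.0
    coords = g[fav]
    weights = np.abs(field.values[fav])
    centres = _adaptive_kmeans(coords, weights, cutoff, cfg)
    return [PharmacophorePoint(FeatureType.HYDROPHOBIC, c, w) for c, w in centres]


def cluster_directional_field(field: GridField, site_positions: np.ndarray, cutoff: float,
                              config: PharmGenConfig | None = None) -> list[PharmacophorePoint]:
    """Patch favorable points by nearest protein group, then cluster per patch."""
    cfg = config or PharmGenConfig()
    site_positions = np.asarray(site_positions, float)
    if len(site_positions) == 0:
        return []
    g = field.grid_coords()
    fav = field.values < 0.0
    coords = g[fav]
    weights = np.abs(field.values[fav])
    if len(coords) == 0:
        return []
    from scipy.spatial import cKDTree

    _, patch = cKDTree(site_positions).query(coords)
    points: list[PharmacophorePoint] = []
    for pid in np.unique(patch):
        mask = patch == pid
        centres = _adaptive_kmeans(coords[mask], weights[mask], cutoff, cfg)
        for c, w in centres:
            points.append(PharmacophorePoint(field.probe, c, w, patch_id=int(pid)))
    return points


def build_forbidden(receptor: MolecularGraph, box: BindingSiteBox,
                    spacing: float = 0.8) -> np.ndarray:
    """Grid positions inside the box that fall within a protein heavy atom's
    van der Waals radius; the exclusion volume for the clash filter."""
    origin, dims = _make_grid(box, spacing)
    field = GridField(spacing, origin, dims, np.zeros(int(np.prod(dims))), FeatureType.FORBIDDEN)
    g = field.grid_coords()
    heavy = receptor.heavy_indices()
    if not heavy:
        return np.empty((0, 3))
    from scipy.spatial import cKDTree

    coords = receptor.coords[heavy]
    radii = np.array([receptor.atoms[i].vdw_radius for i in heavy])
    tree = cKDTree(g)
    inside = np.zeros(len(g), dtype=bool)
    for rad in np.unique(radii):
        for hit in tree.query_ball_point(coords[radii == rad], r=float(rad)):
            inside[hit] = True
    return g[inside]


def build_models(receptor: MolecularGraph, box: BindingSiteBox,
                 config: PharmGenConfig | None = None
                 ) -> tuple[PharmacophoreModel, PharmacophoreModel]:
    """Build the sparse sampling model and the dense ranking model.

    The sampling model keeps only hydrophobic (1.5 A cutoff) and hydrogen-bond
    (2.0 A) points; the ranking model keeps all types at a 1.0 A cutoff. Both
    share one forbidden set.
    """
    cfg = config or PharmGenConfig()
    forbidden = build_forbidden(receptor, box, cfg.forbidden_spacing)

    fields = {}
    for probe in (FeatureType.DONOR, FeatureType.ACCEPTOR, FeatureType.HYDROPHOBIC,
                  FeatureType.AROMATIC, FeatureType.POSITIVE, FeatureType.NEGATIVE):
        fields[probe] = score_grid(receptor, box, probe, config=cfg)

    def directional(probe, cutoff):
        sites = protein_sites(receptor, probe)
        pos = np.array([s.position for s in sites]) if sites else np.empty((0, 3))
        return cluster_directional_field(fields[probe], pos, cutoff, cfg)

    sampling_points = (
        cluster_hydrophobic_field(fields[FeatureType.HYDROPHOBIC],
                                  cfg.sampling_cutoff_hydrophobic, cfg)
        + directional(FeatureType.DONOR, cfg.sampling_cutoff_hbond)
        + directional(FeatureType.ACCEPTOR, cfg.sampling_cutoff_hbond)
    )
    ranking_points = (
        cluster_hydrophobic_field(fields[FeatureType.HYDROPHOBIC], cfg.ranking_cutoff, cfg)
        + directional(FeatureType.DONOR, cfg.ranking_cutoff)
        + directional(FeatureType.ACCEPTOR, cfg.ranking_cutoff)
        + directional(FeatureType.AROMATIC, cfg.ranking_cutoff)
        + directional(FeatureType.POSITIVE, cfg.ranking_cutoff)
        + directional(FeatureType.NEGATIVE, cfg.ranking_cutoff)
    )
    sampling = PharmacophoreModel(
        sampling_points, forbidden, "sampling",
        {"HYDROPHOBIC": cfg.sampling_cutoff_hydrophobic,
         "DONOR": cfg.sampling_cutoff_hbond, "ACCEPTOR": cfg.sampling_cutoff_hbond})
    ranking = PharmacophoreModel(
        ranking_points, forbidden, "ranking",
        {t.name: cfg.ranking_cutoff for t in FeatureType if t != FeatureType.FORBIDDEN})
    return sampling, ranking


# ---------------------------------------------------------------------------
# pharmacophore file format
# ---------------------------------------------------------------------------

def write_model(model: PharmacophoreModel, path: str | Path) -> None:
    """Plain-text pharmacophore file: `type x y z weight patch_id` per line."""
    lines = [f"#density {model.density_label}"]
    cut = " ".join(f"{k}={v:.4f}" for k, v in sorted(model.cutoffs.items()))
    lines.append(f"#cutoffs {cut}")
    for p in model.points:
        x, y, z = p.position
        lines.append(f"{p.type.name} {x:.4f} {y:.4f} {z:.4f} {p.weight:.4f} {p.patch_id}")
    for pos in model.forbidden:
        lines.append(f"FORBIDDEN {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f} 0.0000 -1")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> PharmacophoreModel:
    density = "sampling"
    cutoffs: dict = {}
    points: list[PharmacophorePoint] = []
    forbidden: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#density"):
            density = line.split(maxsplit=1)[1]
        elif line.startswith("#cutoffs"):
            for tok in line.split()[1:]:
                k, v = tok.split("=")
                cutoffs[k] = float(v)
        else:
            tok = line.split()
            ftype = FeatureType[tok[0]]
            pos = np.array([float(tok[1]), float(tok[2]), float(tok[3])])
            if ftype == FeatureType.FORBIDDEN:
                forbidden.append(pos.tolist())
            else:
                points.append(PharmacophorePoint(ftype, pos, float(tok[4]), int(tok[5])))
    fb = np.array(forbidden) if forbidden else np.empty((0, 3))
    return PharmacophoreModel(points, fb, density, cutoffs)
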