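# Methods

This note documents the models implemented in `pharmdock`, the defaults and
their rationale, the numerical choices, and what the synthetic test systems
do and do not establish.

## Protein-based pharmacophore models

A pharmacophore point marks a position where a ligand feature of a given
type would interact favorably with the receptor. Points are derived from
grid fields, one per probe type, over the binding-site box.

**Binding site.** From a reference ligand: the heavy-atom bounding box
expanded by 3 Å per side. A user-supplied axis-aligned box is used verbatim.

**Fields.** Grid spacing 0.4 Å. Each probe accumulates a block-function
term over the complementary protein groups; B(x; x₁, x₂) is 1 for x ≤ x₁ and
decays linearly to 0 at x₂, giving smooth, bounded, parameter-sparse
potentials in the ChemScore tradition:

| probe | protein group | term |
|---|---|---|
| DONOR (polar H) | acceptors (O/N/S with lone pair) | −B(\|d−1.85\|; 0.25, 0.65) · B(Δα; 30°, 80°) |
| ACCEPTOR | donor hydrogens | same form, distance from the H, angle about the X–H axis |
| HYDROPHOBIC | apolar heavy atoms | −B(r − r_vdw,sum; 0.5, 3.0) |
| AROMATIC | ring centres | −B(\|r−3.7\|; 0.25, 0.65) |
| POSITIVE / NEGATIVE | opposite formal charges | −B(\|r−2.8\|; 0.25, 0.65) |

Δα is the deviation from linear hydrogen-bond geometry measured at the
protein group (the ideal probe position lies on the extension of the
anchor→group axis); for pseudo-atom sites without a bonded anchor the
angular term is dropped. Per-interaction weights default to 1.0: fields feed
clustering, where only relative magnitude matters.

**Steric clamping.** Grid points inside the protein van der Waals volume
are zeroed. For heavy-atom probes (all but DONOR) an additional 1.0 Å
clearance beyond the vdW radius is excluded: a ligand heavy atom cannot sit
at the vdW surface itself, and without this clearance cluster centres fall
inside the 1.3 Å forbidden shell where every placement would clash. The
DONOR probe is a hydrogen and keeps the bare vdW clamp.

**Clustering.** Strictly favorable (< 0) points only. The hydrophobic
field is clustered globally; directional fields are first partitioned into
patches by nearest protein group (each point then carries its patch id) and
clustered within each patch. k-means (k-means++ initialisation, one
restart, fixed seed, ≤ 100 iterations) is run for k = 1, 2, … until the mean
nearest-neighbour distance among centres drops below the type cutoff, capped
at 60 clusters per field/patch (the open hydrophobic support would otherwise
demand unbounded centre counts on open pockets; the cap is logged when hit).
Each cluster is reported as its |score|-weighted centroid with weight
Σ|score|.

**Densities.** Sampling model: hydrophobic at 1.5 Å, donor/acceptor at
2.0 Å — sparse enough to keep clique detection tractable. Ranking model:
all six types at 1.0 Å — dense enough to describe the full interaction
pattern. Both share one forbidden set, materialised at 0.8 Å subsampling
(the clash test needs roughly one point per 1.3 Å ball; full 0.4 Å density
would quadruple memory for no benefit).

**File format.** One point per line, `type x y z weight patch_id`, with
`#density` and `#cutoffs` headers and forbidden points as `FORBIDDEN` lines;
round-trips bit-exactly at 4 decimals.

## Ligand side

Conformers come from a multi-record SDF/MOL2 file (canonical path; energies
from the `energy_kcal` tag) or from RDKit's ETKDG embedder with MMFF94
energies as an internal fallback — the fallback is a convenience generator,
not a conformational-search method. At most 100 conformers within
15 kcal/mol of the minimum are kept, lowest-energy first. Duplicates are
removed greedily (keep-first on the energy-sorted list, so the lowest-energy
representative survives) using superposed heavy-atom RMSD with a cutoff by
rotor count: 0.2 Å (0–3 rotors), 0.3 Å (4–6), 0.4 Å (> 6); the boundary is
inclusive (a pair at exactly the cutoff collapses).

Features per conformer: donors at polar hydrogens bonded to O/N/S;
acceptors at O/N/S with ≥ 1 lone pair by valence accounting (this excludes
pyrrole-type and quaternary nitrogen); hydrophobic candidates at heavy atoms
that are neither donors/acceptors nor bonded to one (halogens and sulfur
qualify — the rule is applied literally); aromatic points at ring centroids;
ionic points at the centroid of the charged atom plus its hydrogens.
Hydrophobic candidates are merged agglomeratively — repeatedly fusing the
two clusters with the closest centres while any centre pair is below 2.0 Å —
so the output guarantees ≥ 2.0 Å centre separation by construction (an
off-the-shelf linkage criterion bounds merge distance, not centre distance,
which is why this is hand-rolled).

**Rotatable bonds** (used only for the dedup bins and MC torsions):
non-ring single bonds between heavy atoms with ≥ 1 further heavy neighbour
on each side; amide C–N excluded. RMSD is computed over heavy atoms without
graph-symmetry correction; a symmetry-aware variant was considered and left
out because only relative comparisons at fixed atom order are needed.

## Pose sampling

Nodes of the correspondence graph are type-compatible (ligand feature,
protein point) pairs restricted to donor/acceptor/hydrophobic; an edge joins
two nodes sharing no ligand feature and no protein point whose ligand-side
and protein-side distances agree within 0.3 Å. Maximal cliques of ≥ 3 nodes
are enumerated by Bron–Kerbosch with pivoting; output is sorted (size
descending, then lexicographic) and capped at 50 000 cliques per conformer
with a loud log. Only maximal cliques are placed: a sub-clique's Kabsch
superposition is either identical to its parent's or strictly worse
constrained, so enumerating all sub-cliques would only duplicate placements.

Kabsch superposition is reflection-free (det +1 enforced via the sign of the
SVD determinant); collinear cliques raise and the pose is skipped with a log
entry. After rigid placement, a pose is rejected iff *more than* 10 % of its
heavy atoms lie within 1.3 Å of a forbidden point (strict inequality: 1 of
10 passes). Near-duplicate poses from different cliques (in-place heavy-atom
RMSD ≤ 0.5 Å) are merged keeping the larger clique, since duplicates
otherwise crowd the refinement budget.

## Scoring and refinement

The pharmacophore score S weighs each ligand feature's distance r to its
nearest same-type protein point of the dense model: f(r) = 1 (r ≤ 0.5 Å),
2(1 − r) (to 1.0 Å), 0 beyond; class sums (donor+acceptor → hbond,
± charges → ionic) are combined with weights −0.7/−0.4/−0.6/−0.6. All
ligand features contribute, not only clique members, and a protein point may
serve several features (independent nearest-neighbour lookups).

The PLP potential sums over ligand-heavy × receptor-heavy pairs, each
H-bond or steric by the four-class typing (donor/acceptor/both/nonpolar).
Pair parameters (A, B, C, D, E, F): H-bond (2.3, 2.6, 3.1, 3.4, −2.0, 20),
steric (3.4, 3.6, 4.5, 5.5, −0.4, 20) — the classic PLP parameterisation,
configurable. The piecewise-linear form is evaluated by interpolation
through the knots (0→F, A→0, B→E, C→E, D→0), which is continuous by
construction.

Monte Carlo (per pose, default 1000 steps, seeded): torsion twists (damped
by the branch-size ratio above), a rigid rotation about the centroid
(≤ 15°), and a translation (≤ 0.5 Å per axis); defaults chosen as small
local perturbations consistent with a 60° maximum torsion change. Decision
order: > 3.5 Å in-place RMSD from the start → reset to the start pose; new
global minimum → accept; otherwise accept iff exp(−ΔE·s/RT) exceeds a
uniform draw (strict), with RT = 595.8 cal/mol and a scale s = 1000 coupling
the dimensionless PLP units to cal/mol at kcal-like magnitudes (the units
coupling is a package choice; s is configurable). A reset also follows three
consecutive rejections, restoring the start coordinates and reference score;
resets count as rejections in the acceptance history. Step sizes are
multiplied by 0.9/1.1 when the last-100-step acceptance rate leaves the
[0.4, 0.6] band, clamped to [0.05×, 4×] of the base sizes. The best pose
seen is returned, so refinement is monotone in energy.

The final library ranking uses the best refined PLP energy per ligand; S is
reported alongside but not used for ranking.

## Biased modes

*Confined*: sampling and ranking models are replaced by the selected subset
(selection by id, by typed reference position within a 0.75 Å snap radius —
the format the CLI's selection file uses — or by predicate); forbidden
points are always kept, so clash testing is never relaxed. The search box
itself is not shrunk. *Constraint*: the full site is sampled; after scoring,
poses survive only if at least one ligand feature matches a selected point
within 1.0 Å — the support of f(r), so the constraint uses the same spatial
tolerance as scoring.

## Synthetic test systems

`fixtures.make_toy_system` builds a pseudo-atom pocket (carbonyl-like
acceptor units, N–H donor units, apolar tripods), derives its own
pharmacophore model, and then constructs a pseudo-ligand whose features sit
*exactly on model points* (donor hydrogen on a DONOR point, bare oxygen on
an ACCEPTOR point, carbons on clash-free HYDROPHOBIC points, plus a filler
carbon ring that raises the heavy-atom count to ≥ 10 and carries 0–3
requested rotors). The constructed coordinates are the planted pose; the
docking input is a seeded random rigid displacement of it. Everything is a
pure function of (spec, seed).

These systems make the planted pose the engineered optimum of both scores,
so pipeline tests check recovery (< 0.5 Å at rank 1), determinism, and mode
semantics. They deliberately do not emulate real chemistry: bond lengths
and valences of the pseudo-molecules are unphysical, pockets are open and
rigid, there is no solvent, no tautomery, no conformational strain. Passing
them demonstrates algorithmic correctness — matching, superposition,
filtering, scoring, refinement bookkeeping — not predictive accuracy on
experimental complexes.

Test and example runs use scaled-down settings (20 refined poses at 200 MC
steps rather than 100 × 1000) — the toy landscape is small enough that the
planted optimum is found well within that budget.

## Known limitations

- Rigid receptor; cofactors (HETATM) act as steric obstacles only, with no
  interaction parameters; no metals, no waters, no solvation term.
- The internal conformer generator is a fallback; file-based ensembles are
  the reproducible path.
- The block-function parameters of the grid potentials are package defaults
  in the ChemScore style, collected in one config block and documented here;
  they shape model geometry but all downstream constants (cutoffs, weights,
  tolerances) are independent of them.
- Adaptive k-means is capped at 60 clusters per field/patch; extremely large
  or open sites may saturate the cap (logged) and under-resolve hydrophobic
  detail.
- Heavy-atom RMSD is not symmetry-corrected; for highly symmetric ligands
  reported pose RMSDs can overestimate the true deviation.
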