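# Methods

This note documents the models implemented in `actsite`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Templates and local sites

A template is an ordered set of m ≥ 2 heavy atoms taken from an annotated
enzyme active site. Each source residue carries one of four roles that
decide its contribution: catalytic-site and modified residues contribute
sidechain atoms only; cofactor-binding-site residues contribute all atoms;
mainchain-catalytic residues contribute N, CA, C, O. Sidechain is defined as
heavy atoms excluding {N, CA, C, O, OXT}; hydrogens are ignored throughout.
A glycine annotated as catalytic-site has no sidechain and falls back to its
mainchain atoms (with a warning) — observed template tables do list glycine
by its mainchain. Within a residue, atoms follow the PDB v3 standard order
so the feature ordering is reproducible; across residues, the annotated
listing order is kept. Alternate locations other than blank/'A' are dropped and only the
first NMR model is read; insertion codes are part of residue identity.

A local site is an ordered atom set in a target structure in one-to-one
correspondence with a template's atoms, carrying a label (+1 active for the
template's function, −1 otherwise, unknown when no annotation exists).

## Local site search

Search enumerates, per template residue, the protein residues with the same
residue name containing all required atom names, and assembles combinations
of distinct residues by backtracking. Two pruning/filtering rules apply:

* pairwise-distance compatibility before any superposition —
  |d_site − d_template| ≤ 2·c·√m for cutoff c. If the post-superposition
  RMSD is ≤ c, each atom moves at most c·√m, so each pair distance changes
  by at most 2c√m: the bound is provably sound (never discards a true hit),
  deliberately trading speed for soundness;
* RMSD (√UMD) ≤ c after optimal superposition, c = 4.0 Å by default.

Chemically indistinguishable sidechain atoms (ASP OD1/OD2, GLU OE1/OE2,
ARG NH1/NH2, LEU CD1/CD2, VAL CG1/CG2 and the PHE/TYR ring pairs, swapped as
a unit) generate alternative correspondences; the lowest-RMSD mapping per
residue combination is kept. Residue identity matching is exact — no
substitution groups. Output order is canonical (by chain/residue identity),
independent of atom record order.

## Deviation measurements

UMD is RMSD²: the mean squared atom distance under the optimal proper rigid
motion, computed in closed form by the Kabsch/SVD Procrustes solution.
WMD generalizes it with importance weights β on the simplex:
weight-scaled centroids and cross-covariance, the same SVD, reflection
corrected by flipping the smallest singular direction. With uniform β, WMD
equals UMD exactly. For m = 2 or collinear configurations the rotation is
not unique; the transform is flagged accordingly but the deviation value is
still well defined, which is what the measurements contract on. Rotation
orthogonality/determinant checks use a 1e-8 tolerance (double-precision SVD
accuracy).

## DALI-score measurements

MDS and DSDS compare intra-set distance matrices, avoiding superposition
entirely (and hence keeping the learning problem single-level). The pair
score is the published DALI elastic form with similarity threshold 0.20 and
envelope width 20 Å; both constants are exposed as function parameters in
case a variant is needed. The d* = 0 singularity is defined by its
continuity limit, 0.20. MDS averages the scores over all m(m−1)/2 pairs;
DSDS is an inner product with learned coefficients, no bias — the learned
threshold is kept as a classification diagnostic only, since both analyses
use the measurements as rankings.

## Learning WMD (bi-level program)

The objective is a cost-weighted hinge loss over (β, θ): positives should
deviate below θ − ε, negatives above θ + ε, with per-site costs 1/n₊ and
1/n₋ balancing the strong class skew. Because the deviation itself minimizes
over rigid motions, the problem is bi-level; it is solved by alternating

1. an **LP stage**: with transforms frozen, each deviation is linear in β,
   and the hinge minimization over (β ∈ simplex, βᵢ ≤ 2/m, θ free) is a
   linear program, solved exactly (HiGHS);
2. a **transform stage**: with β frozen, each site's optimal transform is a
   weighted Procrustes problem in closed form.

Transforms are initialized at the unweighted (UMD) optima — the natural
β-uniform starting point — and the stages alternate for 2 iterations by
default. The LP objective is non-increasing across the repeated LP solves,
but the total loss is not guaranteed to decrease across full iterations
(the transform stage can raise negative-site losses); the scheme is a local
heuristic. The margin ε defaults to 0.01 Å² — small against the Å²-scale
deviations; it affects only margin sharpness, not the ranking behaviour.
LP degeneracy is expected; any optimal vertex is accepted and tests compare
objective values rather than argmin vectors.

## Learning DSDS (cost-weighted SVC)

The objective ½‖w‖² + Σⱼ Cⱼ·hingeⱼ with unit margin (ε = 1) and costs
1000/n₊, 1000/n₋ is exactly the soft-margin linear SVC with per-sample
weights and bias −θ, and is solved by `sklearn.svm.SVC(kernel="linear",
C=1)` with sample weights. For a general ε > 0, substituting w = ε·w′
reduces the problem to the unit-margin case with weights Cⱼ/ε, and the
solution is scaled back. No feature standardization is applied — DALI scores
are already bounded — though the features can be standardized upstream if
desired.

## Post-processing

* **LR**: a per-template maximum-likelihood logistic fit of
  P(active | measurement) on the measurement's native scale, with a tiny
  ridge (1e-6) so complete separation — common on well-separated templates —
  yields bounded coefficients (with a warning) instead of divergence.
* **PINTS-style significance** (deviations only): negative-site √WMD (or
  √UMD) values are fitted per template with a Gumbel (minimum) location-
  scale model, and a candidate deviation r is reported as
  log F = log(n_neg · P_null(deviation ≤ r)) − penalty(m).
  The extreme-value family is the natural choice for the left tail of a
  best-match null. The size penalty makes equal deviations of larger
  templates more significant (rarer by chance); the default hook charges
  log 2 per matched atom and is replaceable — it is a documented heuristic,
  not a fitted abundance model. The log-CDF is computed via log1p so the
  ranking stays strictly monotone across the null's support. Applying this
  scheme to similarity measurements is rejected as a configuration error.
* **Direct**: raw values, comparable across templates only within one
  measurement family (enforced).

Merged rankings keep duplicate rows when one site is hit by several
templates, and break confidence ties by (structure id, residue list) for
determinism.

## Evaluation

ROC is the Mann–Whitney statistic (ties half-credit); the curve uses the
standard single-step convention for tied scores, so ties contribute
diagonal (trapezoidal) segments. ROC5 integrates TPR over the first five
false positives and normalizes by 5·n₊ (with fewer than five negatives, all
are used, and ROC5 equals ROC at exactly five). Sensitivity at 95%
specificity uses the conservative convention: the TPR at the largest
achievable FPR ≤ 0.05, with no interpolation. Splits are 50/50 at structure
level, repaired by swapping structures (never moving a sole remaining
carrier) until every template keeps at least one positive-bearing training
structure; plans are deterministic given the seed. Single-template analysis
pools test sites per template; multiple-template analysis computes one
curve per test protein over its (site, template) rows, skipping proteins
lacking one of the classes. Percentile ROC curves are taken pointwise on a
common FPR grid after linear interpolation.

## Synthetic benchmark

The generator plants rigid-transformed copies of a template with per-atom
Gaussian displacement: positives use a heterogeneous profile (default
benchmark: m = 6, two conserved atoms at σ = 0.05 Å, four variable at
σ = 0.8 Å), decoys use σ = 1.5 Å on all atoms (optionally a distance-matrix
shuffle), and both share the template's residue composition so the search
cannot dismiss decoys trivially. Class skew defaults to 50 positives : 500
negatives, exercising the 1/n± and 1000/n± cost weighting. Fixture proteins
scatter decoy residues of the template's types at ≥ 2.5 Å separation inside
a 60 Å box around an optionally planted noisy copy.

What this emulates: heterogeneous positional conservation, hard negatives
reachable by search, severe class imbalance, structure-level train/test
leakage control. What it does not: real backbone geometry and rotamers,
correlated (non-isotropic) atomic displacements, homology structure between
decoys, residue-type confusions, or crystallographic artifacts. Passing the
benchmark shows the estimators recover planted signal under the assumed
noise model — not that they match any particular performance level on real
curated enzyme data, whose headline numbers depend on a large annotated
structure corpus outside this package's scope.

## Problem sizes and numerics

The shipped experiment driver and the reproduction script use 3 templates,
6 atoms each, 550 sites per template over 25 pseudo-structures and 5
repeated splits — sizes chosen so a full run completes in seconds on one
core while every code path (all four measurements, all three
post-processings, split repair, per-protein evaluation) is exercised with
stable averages. LP solver tolerance is HiGHS defaults (~1e-9 feasibility);
weight vectors are re-projected onto the simplex after solving to remove
solver round-off. Degenerate inputs (m = 2 sites, collinear atoms,
zero-distance pairs, complete separation, all-tied scores) are all defined
and tested rather than left to chance.
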