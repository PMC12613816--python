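# Methods

This note documents the models, defaults and numerical choices behind
`phoreseek`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## Interaction perception

A protein–ligand complex is reduced to typed geometric contacts:

| kind | criterion (defaults) |
| --- | --- |
| hydrogen bond (ligand donor / acceptor) | heavy-atom D···A ≤ 3.5 Å and D–H···A ≥ 130° when hydrogens are present; distance-only fallback otherwise |
| hydrophobic | apolar C···C ≤ 4.5 Å |
| ionic | opposite charged-center distance ≤ 5.5 Å |
| aromatic (π) | ring-centroid distance ≤ 5.5 Å with inter-plane angle ≤ 30° (stacked) or ≥ 60° (T-shaped) |

These are standard structural-biology cutoffs; the literature that uses
this interaction vocabulary rarely prints its numeric thresholds, so all
of them are exposed in `GeometricRules` rather than hard-coded.

Protein-side donors, acceptors, charges, apolar carbons and aromatic rings
come from a fixed residue template table (Lys/Arg positive, Asp/Glu
carboxylate negative, backbone N donor / O acceptor, side-chain carbon
sets per residue). No pKa or protonation-state prediction is attempted —
formal charges are taken as annotated. Ligand chemistry is inferred from
elements, formal charges and covalent-distance bond perception, or, for
SDF input, from RDKit's feature factory. Ligand aromatic-ring carbons are
typed as aromatic rather than hydrophobic, following pharmacophore
practice; protein-side ring carbons remain apolar so alkyl-vs-aryl
contacts are still perceived.

Events are deduplicated at (kind, ligand atom set, residue) granularity
and ordered deterministically. Detection is equivariant under rigid
motions and monotone under threshold tightening; both are property-tested.

## Pharmacophore models and consensus

A per-complex model places one feature sphere per interaction event
(HBA/HBD/HYD/PI/NI/AR), radius 1.5 Å by default — the customary tolerance
sphere — anchored to the interacting residue. Models are overlaid by
least-squares rigid superposition (Kabsch); the same-kind correspondence
set is chosen by exhaustive enumeration over maximal per-kind injective
assignments, which is exact and cheap at pharmacophore sizes (≲ 8
features).

The consensus of overlaid models clusters features per kind by greedy
centroid linkage within a 1.5 Å merge radius (equal to the default
tolerance). Clustering runs in a canonical feature order — kind, then
position, then source index — so the result is independent of the order
models are supplied. A cluster is retained iff it contains features from
strictly more than `min_models` distinct sources (default 4 of 8,
matching a "present in more than four models" retention rule); a flag
switches to at-least semantics. Retained features take the member
centroid, the maximum member tolerance and the union of anchors.
Direction vectors are carried through but do not participate in
membership, as no directional merge rule is defined for this model class.

## Matching and screening

Conformers are consumed as feature-point sets (from the JSON library
schema, the synthetic generator, or RDKit-perceived SDF conformers);
conformer *generation* is deliberately out of scope. Candidate
correspondences come from the classic correspondence-graph formulation:
nodes are kind-compatible feature pairs, edges require
|d_model − d_conformer| ≤ (tol_i + tol_k) · scale, and maximal cliques
(networkx) are the candidate mappings; a test-side brute-force enumeration
over all injections verifies exactness. Each candidate is rigidly fitted;
a pair is valid when its post-fit distance is within the (scaled) model
tolerance.

The score is artifact-defined — `n_valid − rmsd_valid / mean(tolerance)` —
monotone up in satisfied features and down in deviation; only rankings are
meaningful. The hit rule mirrors screening-tool settings: at least
`min_required_features` (default 3) valid pairs and at most
`max_omitted_features` (default 0) unsatisfied model features, so the
defaults demand a full match. Both knobs exist even though 0-omitted makes
the minimum redundant at default model sizes, because both are
user-visible settings in the workflow being reproduced.

Degenerate (collinear) candidate mappings cannot be rigidly fitted and are
skipped during best-match selection; ties break by lower RMSD, then
lexicographic mapping.

## Validation statistics

Confusion counts treat actives as positive and inactives + decoys as
negative; 0/0 rates are reported as undefined rather than coerced. ROC
curves sweep distinct score values (ties share a step; the no-match
sentinel sorts below every score), AUC is the trapezoid area, and EF(f) is
precision in the top-f fraction over the active base rate. Decoy
selection matches each candidate to some active within per-property
tolerances over the classic sextet — MW ± 25, HBA/HBD counts ± 1,
rotatable bonds ± 1, formal charge exact, apolar fraction ± 0.1 — with a
seeded, deterministic draw when the pool exceeds the requested ratio and
an explicit shortfall report when it cannot be met.

## Dynophores

A trajectory (multi-MODEL PDB; every frame weighted equally) is profiled
by running the identical static detection on each frame. Interaction keys
are (kind, ligand atom set, residue) — stable across frames and the
granularity at which per-residue frequencies are reported. Replicas
concatenate by appending frames and unioning keys (absent keys back-fill
as absent). Occurrence percentages are reported both exactly and rounded
to integer percent, per key and aggregated per kind (a frame counts for a
kind when any key of that kind is present, so the aggregate bounds every
member from above). Clouds collect the site positions of present frames.

## Pharmacology

Concentration–response data follow the four-parameter logistic
r(c) = bottom + (top − bottom)/(1 + (c50/c)^hill), fitted by
Levenberg–Marquardt least squares in log10(c50) with analytic gradients
and three starts (hill = +1, −1, +2) to avoid the Hill-sign local minimum;
the fit is canonicalized afterwards (bottom ≤ top, hill > 0 — an exact
reparameterization). Confidence intervals are asymptotic t-based on
log10(c50), top and hill; a residual-bootstrap percentile interval on
log10(c50) is available behind a flag for small designs. Non-convergence
is reported in-band.

Dose ratios are EC50 ratios against the control curve (the standard choice
with 4PL fits; equi-active concentration ratios are the noted
alternative). The Schild regression fits log10(DR − 1) on log10[B] by OLS
for DR > 1 points (DR ≤ 1 points are excluded with notice);
pA2 = intercept/slope (the magnitude of the x-intercept), and the
unity-constrained estimate is pK_B = mean(log10(DR − 1) − log10 B).
Competitive behavior is diagnosed when the slope CI covers 1 and the top
parameters of all treated curves overlap the control's 95% CI (the
"unchanged Emax" argument); Hill-slope CI overlap serves as the
parallel-shift check. A purely non-competitive dataset produces no
rightward shift, so the regression correctly raises a no-antagonism error
while the Emax diagnostic (exposed standalone) trips.

## Synthetic data

Generators use NumPy's Philox counter-based RNG with explicit integer
seeds; identical specs give identical bytes.

* **Pockets** plant each requested interaction at a well-separated site
  (≥ 12 Å apart) just inside its threshold (H-bond 2.9 Å/≈180°,
  hydrophobic 4.0 Å, ionic 5.0 Å, ring stack 3.8 Å/0°), with an inert
  scaffold and a seeded rigid motion of the whole complex; ground truth is
  re-detected and compared before returning.
* **Trajectories** displace a plant's ligand atoms 5 Å along the contact
  axis in scheduled-off frames and add 0.02 Å Gaussian jitter everywhere —
  small against the ≥ 0.2 Å geometric slack, and validated post hoc frame
  by frame (a noise level that flips any scheduled state is an error, not
  a silent artifact).
* **Libraries** give each active exactly one conformer that matches the
  query (model features under 0.3 Å Gaussian jitter by default,
  rejection-sampled to guarantee the match) among otherwise scrambled
  conformers; decoys and inactives are kind-preserving geometric scrambles
  rejection-sampled to never match at scale 1, with properties drawn
  within decoy-matching tolerance of an active. Shipped shapes mirror
  published validation designs (158/231/8406 and 47/231/2538
  actives/inactives/decoys) with 3 conformers per molecule; the conformer
  count is a free parameter and a 25-conformer contract is tested
  separately.
* **Dose–response** data shift EC50 by (1 + B/K_B) (competitive) or scale
  the top by 1/(1 + B/K_B) (non-competitive), with per-observation
  Gaussian noise. The Schild benchmark uses K_B = 100 nM, B ∈ {1, 3, 10,
  30}·K_B, 11 agonist concentrations spanning the shifted range, noise
  sd = 5 assay units (5% of the 0–100 range), 2 replicates.

### What the synthetic benchmarks do not show

Planted pockets realize one clean geometry per interaction; real
complexes have correlated, marginal and water-mediated contacts, and the
perception rules here will not reproduce a proprietary engine's feature
lists atom for atom. Scrambled decoys are geometrically, not chemically,
decoy-like: perfect retrieval on them demonstrates the matching engine's
correctness, not prospective enrichment on vendor libraries. Planted
trajectories have binary, independent frame schedules rather than MD
kinetics. Published campaign numbers that depend on external compound
collections or long MD runs are therefore treated as design mirrors, not
as reproduction targets.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
of compute apart from the two simulation studies: the set-B-shaped screen
(2,585 molecules × 3 conformers), the 3 × 1000-frame dynophore benchmark,
the 500-instance matching-vs-brute-force audit and the 200-seed Schild
calibration each complete in seconds on one core.
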