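# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind each stage of the toolkit.

## Torsion coupling (site nomination)

**Model.** Statistical coupling between two residues is measured as plugin
(histogram) mutual information, in nats, between their discretized torsion
distributions across an ensemble of conformations:
`MI = Σ p(x,y) ln[p(x,y)/(p(x)p(y))]`. Backbone φ/ψ and side-chain χ1–χ4
torsions enter; ω is extracted but excluded by default (nearly constant at
180°, contributing only estimator noise). Torsions whose circular spread is
below 1° are treated as constant and skipped.

**Binning.** Fixed-width 24 bins of 15° over [−180°, 180°). Fixed-width
binning is exactly reproducible and separates the canonical rotamer wells
(gauche−/gauche+/trans) cleanly; adaptive-partitioning estimators were
deliberately left out of scope.

**Significance and correction.** Plugin MI is biased upward by roughly
(B₁−1)(B₂−1)/(2n) nats for occupied bin counts B. Each inter-residue
torsion pair therefore gets a frame-permutation null (default 100
permutations; one series' frames are shuffled, destroying cross-dependence
while preserving marginals). A pair contributes only when observed MI
exceeds the null's 95th percentile, and contributes the *excess*
MI_observed − null_mean. The 95th percentile uses the upper order statistic
of the permutation sample rather than an interpolated quantile: the
interpolated estimate has exceedance probability (m−r+1)/(m+1) ≈ 6–7% at
m = 60–100 permutations and would make the nominal 5% test anti-conservative.
Residue-pair coupling is the sum of excess MI over that residue pair's
significant torsion pairs; the matrix is symmetric with a zero diagonal.

**Multiple runs.** Independent simulation copies of the same system are
accepted as a list of ensembles and concatenated along frames after
per-ensemble topology validation, pooling sampling before estimation.

**Site grouping.** Average-linkage hierarchical clustering of the distance
matrix `max(MI) − MI`, cut at the distance corresponding to a minimum
coupling threshold (default 0.05 nats); groups of ≥ 2 residues whose mean
internal coupling clears the threshold are reported largest-first.

**Seeds.** Every stochastic operation takes an explicit integer seed and is
a pure function of its inputs.

## Pose seeding

The mobile domain is rotated about its heavy-atom centroid so that its
site-patch→centroid axis anti-aligns with the static domain's, making the
two nominated patches face each other, then slid along the static patch's
outward axis until the minimum interdomain heavy-atom distance equals the
contact gap (default 4 Å), solved by bisection to 0.1 Å. By construction the
two domain centroids and patch centroids are collinear after placement. A
patch whose domain extends more than 2 Å beyond it along its own outward
axis triggers a buried-site warning; failure to reach the contact gap along
the axis is an error.

## Gaussian perturbation sampling

Each pose is an independent perturbation of the seed pose (not a Markov
chain — the move widths are interpreted as the spread of the local search
around the seed). The move set, applied in this order:

| component | distribution | default |
|---|---|---|
| translation along center axis | N(0, σ) | σ = 3 Å |
| translation ⟂ to axis (×2) | N(0, σ) | σ = 8 Å each |
| rotation about center axis | N(0, σ) | σ = 8° |
| tilt of the axis | N(0, σ) about a uniformly random ⟂ axis | σ = 8° |

The center axis is the line through the two domains' heavy-atom centroids
in the seed pose. Rotations pivot at the *translated* mobile centroid, so
the centroid displacement is exactly the drawn translation vector; this
makes every pose decomposable back into its move-set coordinates
(translation components by projecting the centroid displacement onto the
axis frame; the axial angle by swing–twist decomposition of the delta
rotation about the axis, which recovers the drawn angle exactly). The tilt
axis distribution is not dictated by the move set's description; uniform in
the perpendicular plane is the symmetric choice.

No side-chain repacking is attempted, so clash screening *flags* rather
than removes poses by default (count of interdomain heavy-atom pairs under
2.5 Å, flag at > 5 violations); a strict mode drops flagged poses.

## Tether filter

The covalent linker constrains the Cα–Cα distance between the static
domain's C-terminal residue and the mobile domain's N-terminal residue.
Poses beyond the cutoff (60 Å default) are discarded; the comparison is
inclusive, and Cα is the conventional tether proxy since no atom pair is
dictated by the construct. `physical_bound(n)` = n × 3.8 Å gives the
fully-extended upper bound for an n-residue linker (23 residues → 87.4 Å),
a sanity check that the configured cutoff is reachable. Explicit linker
conformations are out of scope.

## Pose clustering

**Metric.** Tethered RMSD: Kabsch superposition of one pose onto another
over static-domain Cα, then plain RMSD over mobile-domain Cα. Since the
static domain never moves in the pose model, the superposition is the
identity and the metric reduces to the mobile-selection RMSD; the general
two-step form is kept (and tested against the brute-force minimizer) for
exactness.

**Cut selection.** Average-linkage agglomeration; at each merge step the
average intra-cluster spread (mean pairwise distance over clusters with
≥ 2 members) and the cluster count are each linearly rescaled onto
[1, n_steps], and the step minimizing their sum is chosen. Representatives
are medoids (member minimizing mean intra-cluster distance). Top clusters
are ranked by size, ties broken by lower spread; ranking by mean
interaction energy is available as a config alternative.

**Known limitation.** The combined penalty structurally favors splitting
large unimodal clusters: the spread term's reward for halving a Gaussian
blob grows with the number of steps while the count term's cost stays +1
per cluster. In practice planted partitions (separation/spread ≥ 5) are
recovered exactly up to roughly 40 members per group; beyond that the cut
may subdivide true groups (members stay together — subdivisions are
refinements, never mixtures). The penalty trace is exported so users can
inspect and override the cut.

## Interface metrics

- **SASA / BSA.** Shrake–Rupley quadrature with a deterministic golden-spiral
  point set (960 points default, 1.4 Å probe, Bondi-type radii C 1.70 /
  N 1.55 / O 1.52 / S 1.80 Å, user-overridable; unknown elements fall back
  to 1.70 Å with a warning). BSA = SASA(A) + SASA(B) − SASA(AB) over heavy
  atoms. This is solvent-accessible, not molecular-surface, area: absolute
  values differ from molecular-surface programs, but the metric's role here
  is ranking, which the monotone relationship preserves.
- **Contacts.** Hydrophobic: unique cross-domain pairs of hydrophobic
  residues (ALA VAL LEU ILE MET PHE TRP PRO TYR) whose side-chain heavy
  atoms approach within 5 Å. Ionic: oppositely signed residues
  (LYS/ARG/HIS vs ASP/GLU) whose charged-group atoms approach within 6 Å;
  salt bridges are ionic contacts annotated with the minimum charged-group
  distance. Residue *pairs* are counted once each (atom-contact counting is
  a plausible alternative the sources leave open).
- **Stacking.** Aromatic pairs with ring-centroid distance in [4.5, 7.0] Å
  (unweighted centroid of the ring heavy atoms). No angular criterion is
  applied — the classifier is a distance monitor, not a geometry validator.
- **Energy.** E_ele = Σ k q_i q_j / (ε_r r_ij) with k = 332.0636
  kcal·Å/(mol·e²), ε_r = 4 (screened protein interior); E_vdw = standard
  12-6 Lennard-Jones with Lorentz–Berthelot combination over generic
  per-element classes (OPLS-like σ/ε for C, N, O, S). Charges are unit
  formal charges spread evenly over each charged side-chain group; all other
  atoms are neutral. The exact pair sum is used (no cutoffs) — desk-scale
  systems make this affordable, and it preserves the identity
  E_complex − E_A − E_B ≡ cross-domain pair sum to 1e-9 (the brute-force
  total energy accumulates in extended precision because the large bonded
  LJ terms cancel in the subtraction). Any heavy-atom pair under 0.5 Å is an
  error: energies in a hard clash are meaningless. This proxy ranks poses;
  its absolute values are not force-field energies, and solvation/entropy
  terms are out of scope.

## Ensemble analytics

RMSF is computed after Kabsch-fitting every frame to frame 0 over the fit
selection, as the per-atom RMS deviation from the *time-mean* position
(the conventional reference; a first-frame reference is the other
defensible choice), aggregated per residue. With isotropic per-coordinate
jitter of SD σ, RMSF → σ√3, which the tests use for parameter recovery.
Segment RMSD series fit each frame to a reference over one selection and
measure Cα RMSD over another; distance monitors support centroid, minimum
and Cα modes. The ranking table reports per model: E_bind mean ± sd over
frames, mobile-domain RMSF after fitting on the static domain (PK_RMSF
style), time-averaged BSA, frame-averaged contact counts rounded half-up to
integers (matching the integer presentation convention), and the RMSF of a
nominated helix (KH_RMSF style, e.g. an αC helix range). Rows are sorted by
mean interaction energy ascending (most favorable first).

## Synthetic fixtures

Generators are pure functions of their parameters and seed.

- `make_helix_domain` builds peptides from ideal bond lengths/angles
  (Engh–Huber-like) by NeRF internal-coordinate placement at constant
  (φ, ψ); construction dihedrals are recovered exactly by torsion
  extraction. Idealized side chains cover A G S V L I K R D E F Y.
- `make_two_domain_complex` plants interface features with exact defining
  distances: the rigid placement is solved by bisection on the first
  feature's defining distance (patch-facing orientation as in pose
  seeding); additional features are verified against their targets, and an
  unsatisfiable combination raises — one rigid placement has a single
  degree of freedom along the approach axis, so only one exact distance can
  be dialed in.
- `make_rotamer_ensemble` hops χ1 between gauche− (−60°) and trans (180°)
  wells with 5° within-well noise; listed residue pairs draw their well
  states jointly from a 2×2 probability table, everything else flips
  independently. The wells sit in distinct 15° bins by construction. The
  backbone is static.
- `make_jitter_ensemble` adds Gaussian per-coordinate noise with a
  per-residue σ profile (fit regions can be left noiseless).
- `make_pose_groups` plants pose families as pure translations (tethered
  RMSD of a pure translation equals its norm) with isotropic jitter of
  total 3-D SD equal to the requested spread.

These fixtures emulate the *statistical* structure of real data — coupled
rotamer jumps, thermal jitter, pose families — not its physics. Passing
tests demonstrate estimator and geometry correctness under known ground
truth; they do not demonstrate that any particular biological complex is
predicted correctly, which requires real ensembles and real structures.

## Problem sizes

Default test and demonstration sizes are chosen for a desk-scale run:
16-residue toy domains, 10,000-pose sampling runs, ensembles of 500–1,500
frames for estimator-recovery checks, 60–100 permutations per null, and
120–960 quadrature points per atom for SASA (coarser in inner loops of
multi-frame tables, finer for single-structure reports).
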