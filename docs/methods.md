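# Methods

## Scope and data model

`scwnet` operates on single configurations ("frames") of rigid four-site
water — two hydrogens, an oxygen carrying the Lennard-Jones centre, and a
massless M site holding the negative charge on the HOH bisector — plus
optional monatomic ions.  It does not run dynamics: frames come from an
external simulation (read from fixed-width GRO-dialect files) or from the
built-in synthetic generators.  Likewise it consumes QTAIM
bond-critical-point (BCP) property tables produced by external
quantum-chemistry tooling; no wavefunctions are handled.

Units are fixed project-wide: nm, nm/ps, kJ/mol, K, bar, e, u.  With
masses in g/mol, (g/mol)·(nm/ps)² = kJ/mol, so kinetic energies need no
conversion factors.

Default force-field parameters are the standard TIP4P/2005 values
(q_H = +0.5564 e, q_M = −1.1128 e, σ_OO = 0.3159 nm, ε_OO = 0.7749
kJ/mol, r_OH = 0.09572 nm, θ_HOH = 104.52°, d_OM = 0.01546 nm,
f_Coulomb = 138.935458 kJ·mol⁻¹·nm·e⁻²); all are overridable through
`ForceFieldParameters`.  Site masses are m_H = 1.00794 u and m_O =
15.9994 u (m_w = 18.01528 u).

## The interaction criterion

A pair (i, j) is connected when

V_Coulomb + V_LJ + E_kin(i,j) + λ·4·E_kin_H < 0   (strict; ties excluded).

Choices that the criterion leaves open, and how they are resolved here:

- **Relative kinetic energy.**  E_kin(i,j) = ½·μ·|Δv_com|² with
  μ = m_w/2, the reduced mass of two equal molecules — the standard
  two-body decomposition of relative-motion kinetic energy.  A
  whole-mass convention (½·m_w·|Δv|²) would simply double the term; the
  reduced-mass form is the package's documented choice.
- **Thermal reference.**  E_kin_H is the kinetic energy of a
  hydrogen-mass particle at the Maxwell–Boltzmann most probable speed
  v_p = √(2RT/m_H).  The mass cancels (E_kin_H = R·T exactly); the
  implementation goes through the velocity formula to keep the
  speed-distribution reading explicit, and a test asserts the identity.
  At T = 1.04·647.096 K this gives 5.60 kJ/mol (2 decimals).
- **The factor 4** counts the hydrogen atoms in a molecular pair and is
  fixed, not configurable.
- **λ** is phenomenological: it absorbs constraints on hydrogen motion
  (covalent O–H binding, cooperative hydrogen bonding) that the explicit
  pair terms miss.  It is calibrated, not derived (see below); the
  package default is 0.655.

Distances are plain Euclidean with no minimum-image convention.
Correctness near the periodic boundary is instead delegated to the
inner-cube filter (below), so edges never wrap across faces.  This keeps
every pair energy an honest function of the stored coordinates.

## Geometric filters

Filters are applied cheapest-first; the order does not change the result.

1. **Inner cube** — only molecules whose COM lies in the concentric cube
   of edge 0.85·L survive as nodes.  This removes the boundary region
   where image interactions would otherwise masquerade as direct ones.
2. **Candidate pairs** — a KD-tree screen keeps COM pairs within
   `pair_cutoff` = 0.8 nm.  The thermal penalty λ·4·E_kin_H (≈ 14.7
   kJ/mol at the default conditions) cannot be overcome by the pair
   potential beyond roughly 0.6 nm, so 0.8 nm is conservative; a
   regression test asserts that raising the cutoff never changes the
   edge set.
3. **Interference cylinder** — a pair is discarded if any third body's
   test point falls inside the finite cylinder of radius r_c along the
   COM–COM segment.  Conventions adopted (both configurable):
   the cylinder is *capped* (axial projection strictly between the
   endpoints — an infinite cylinder would let bodies behind either
   partner veto the pair), the third-body test point is the *COM* (the
   cylinder is defined through centres of mass, so the test point is kept
   consistent with the axis), and *ions count* as blocking third bodies.
   r_c defaults to σ_OO = 0.3159 nm, the effective oxygen diameter.
4. **Energy criterion** — the surviving pairs are kept iff the criterion
   total is negative.

Water–ion pairs are never admitted as network edges: ions act purely as
geometric obstacles.  Networks are therefore water–water graphs.

## Topology metrics

Density (all nodes, Eq. ρ = 2E/(N(N−1))) and density over interacting
(degree ≥ 1) nodes are both reported: dropping isolated molecules shrinks
the denominator at fixed E, so the interacting density is systematically
the larger and the two can trend in opposite directions with temperature.
Average degree is 2E/N and satisfies ⟨k⟩ = ρ·(N−1) identically.
PageRank uses damping 0.85 with uniform teleportation (the classical
setting; no specific damping is mandated by the method), tolerance 1e-10
on the l1 change and a 10,000-iteration cap; isolated nodes are dangling
and redistribute uniformly.  The "PageRank mean" is averaged over
interacting nodes only, since the all-node mean is identically 1/N.

The component-size distribution n_c(s) (monomers included) is fitted to
A·s^b by ordinary least squares on ln n_c vs ln s over sizes with
positive counts; A is the model value at s = 1 and b the slope.  OLS on
raw counts is the default (a count-weighted variant is selectable);
normalized fractions shift only A, not b.  Exact power-law data are
recovered to numerical precision, and under 5% multiplicative noise the
mean recovered exponent stays within 0.05 of truth (200 replicates,
fixed seed) — both are regression-tested.

## λ calibration

`calibrate_lambda` scans a λ grid (default 0 to 1, step 0.001), builds
the networks of all supplied frames at each λ — the λ-independent
geometry and pair energies are computed once per frame and re-thresholded,
which makes the dense default grid cheap — pools component-size counts
across frames, normalizes to fractions, and scores the pooled
distribution against the reference with MAE (RMSE is reported alongside;
MAE is the primary objective).  Distributions are aligned on the union of
sizes with missing entries as zero.  λ* is the MAE argmin; ties resolve
to the smallest λ.  Because edge sets are piecewise-constant in λ, λ* is
identified only up to the grid resolution where the data actually
change; the self-recovery tests use frame ensembles rich enough that
adjacent grid points differ.

## Representative selection

*Frames*: each frame is flattened to a row of x, y, z for H_a, O, M, H_b
per molecule (12·N columns; 102,528 for 8544 molecules), mean-centred
across frames without per-column scaling (all columns share units), and
projected onto the smallest number of leading principal components
explaining ≥ 90% of variance (minimum 2).  The frames with the smallest
norm in the projected space — the centred mean is the origin — are
returned, ties to the lower index.  For degenerate clouds (zero variance
or fewer than three frames) distances are taken in the full centred
space, which coincides with retaining all components.

*Components*: multi-molecule components are summarized by four
descriptors — the sum and population standard deviation (ddof = 0) of
their edge O–O distances, and the mean and standard deviation of their
edge energies.  Edge energy is the pair potential sum V_Coulomb + V_LJ;
the kinetic terms describe instantaneous motion rather than the bond and
are excluded.  Descriptors are z-scored within the size/topology group
(mixed units), projected with a full-rank PCA (an isometry, so distances
equal those in the standardized space), and the component nearest the
origin wins; ties go to the lowest id.

## QTAIM classification

BCP tables are consumed in atomic units.  G ≥ 0 is enforced; a missing
member of (K, V) is derived from V = −G − K and supplied triples must
satisfy the identity within 1e-8.  H = G + V (= −K).  The classifier uses
the sign rules — noncovalent: ∇²ρ > 0 ∧ H > 0; partially covalent:
∇²ρ > 0 ∧ H < 0; covalent: ∇²ρ < 0 ∧ H < 0 — with the −G/V ratio
resolving exact zeros (> 1 noncovalent, (0.5, 1] partially covalent,
≤ 0.5 covalent), following the standard closed-shell/shared-shell
taxonomy.  For V < 0, ratio > 1 ⇔ H > 0, so the two routes agree away
from the boundaries; the combination ∇²ρ < 0 with H > 0 is physically
inconsistent and is flagged rather than raised.  All cutoffs live in
`ClassificationThresholds`.  The label is invariant under positive
rescaling of (G, K, V), which is property-tested.

Cross-condition comparisons use Kruskal–Wallis by default (rank-based,
no normality assumption; the sampling unit is whatever grouped lists the
caller supplies) with one-way ANOVA selectable; the significance
threshold used in reporting is 5.00 × 10⁻².  If every observation is
identical the statistic is undefined and p = 1 is returned with a
warning.

## Synthetic data: what it does and does not emulate

`generate_water_frame` produces thermally agitated but *uncorrelated*
configurations: oxygen positions by rejection sampling at a minimum
separation, independent uniform rigid orientations, and per-molecule COM
velocities drawn from the Maxwell–Boltzmann distribution at T
(equipartition of the sampler is tested at the 2% level on 10⁴
molecules).  Velocities are rigid-body translations only — no rotational
sampling — which suffices because only COM velocities enter the pair
kinetic term.  Random orientations rarely satisfy the criterion, so these
frames are sparse in edges; they exercise the machinery (monotonicity,
calibration, screening invariance), not liquid-state structure.

`planted_cluster_frame` builds isolated linear chains at a prescribed O–O
spacing (default 0.28 nm) with a fixed near-linear hydrogen-bond motif:
the donor O–H lies on the chain axis and consecutive molecules alternate
by a half-turn about it, a geometry whose pair potential (≈ −21.4 kJ/mol
at 0.28 nm) comfortably beats the thermal penalty at the default λ and
T.  Chains sit on a grid with ≥ 1 nm between clusters (beyond the pair
cutoff) and inside the inner cube, so the pipeline must recover the
planted component-size distribution exactly — the module's core
acceptance property.  Within a straight chain, next-nearest pairs are
vetoed by the interference cylinder (the middle molecule sits on the
axis), keeping planted chains topologically linear.  The velocity draws
are seed-stable across temperatures, so raising T_cold scales every
relative kinetic energy up and the recovered edge count is
non-increasing — also tested.  No attempt is made at realistic liquid
structure, cooperative polarization, or cluster-shape diversity.

`synthetic_bcp_table` samples records strictly inside each class region
(noncovalent: ratios in (1.1, 2.0) with positive Laplacian; partially
covalent: ratios in (0.55, 0.95); covalent: ratios in (0.15, 0.45) with
negative Laplacian), with ρ ranges typical of each regime, so a correct
classifier must recover the ground truth exactly.  Passing these tests
shows the decision logic is right, not that real BCP populations are
separable — real tables can sit near the boundaries.

Consequently, passing the synthetic-data test suite demonstrates
correctness of the criterion arithmetic, filters, graph analysis,
calibration and classification logic on configurations with known ground
truth; it does not validate the physical fidelity of any particular
simulation.

## Numerical choices and degenerate inputs

- Strict inequality in the criterion; a pair exactly at zero is not
  connected.
- Coincident charged sites or oxygens raise singularity errors;
  coincident COMs make the cylinder axis degenerate and raise.
- Frame files: positions are wrapped to [0, L) per axis on read
  (orthorhombic boxes only); missing velocities become zero vectors with
  a logged warning; water residues must have 4 sites and ions 1.
  Writing uses %8.3f nm positions and %8.4f nm/ps velocities, and
  write∘read round-trips are byte-stable at that precision.
- Problem sizes in the test and acceptance runs (a few hundred molecules
  per frame, 4–6 frames per calibration, 200 power-law replicates) are
  the package's default desk-scale study conditions; they keep every
  property estimable while the full pipeline stays exact (planted
  recovery, identity checks) rather than approximate.

## Known limitations

- No Ewald/PME electrostatics: pair Coulomb sums are bare, which is the
  point of the interference-free pairwise criterion but is not a
  substitute for full electrostatics.
- No triclinic boxes; no minimum-image edge construction (the inner
  cube is the supported boundary treatment).
- Ion energetics are out of scope; ions only block cylinders.
- Multi-frame trajectory files are read as concatenated single frames;
  stride handling is the caller's responsibility.
- The λ calibration identifies λ* only up to the resolution at which the
  pooled distribution actually changes (edge sets are step functions of
  λ).
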