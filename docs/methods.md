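# Methods

## Shape model and superimposition

A leaf is an ordered configuration of 17 planar landmarks; landmark
identity is fixed by position in the list (petiolar junction, midvein tip,
left/right distal sinuses and lobe tips, left/right proximal sinuses and
lobe tips, petiolar vein termini, and the five vein branch points).
Coordinates are accepted in image convention — y may increase downward and
leaves may be digitized mirrored — and no axis flip is applied on read:
superimposition with reflection permitted (the default) makes the
orientation immaterial, and the convention travels with the dataset's
provenance string.

Pairwise superimposition is the classical orthogonal solution: both
configurations are centered and scaled to unit centroid size (the square
root of summed squared landmark distances to the centroid), and the
orthogonal map Q maximizing trace(QᵀBᵀA) comes from the SVD of BᵀA.
When reflection is forbidden, the smallest singular direction is flipped to
force det Q = +1. The Procrustes distance reported is the residual
root-sum-of-squares between the unit-size configurations after the optimal
map — the quantity a brute-force rotation grid converges to, which is how
the test suite checks it.

Generalized Procrustes analysis iterates this kernel against a consensus:
center (and, with scaling on, unit-size) every configuration, initialize
the consensus as the first configuration, then alternate (i) rotating every
configuration onto the consensus and (ii) replacing the consensus by the
re-normalized arithmetic mean, until the consensus moves less than `tol`
(default 1e-10 root-sum-of-squares, `max_iter` 100 — convergence on
realistic data takes ~6 iterations, and both steps are exact minimizers, so
the summed squared distance to the consensus is provably nonincreasing).
Non-convergence raises an error carrying the final delta rather than
returning a half-aligned set.

**Tangent-plane finishing step.** Unit-centroid-size scaling constrains
shapes to a sphere. Centering and rotation optimality are *linear*
constraints on the aligned coordinates (two translation directions and the
rotated-consensus direction are exactly null), but the sphere is curved, so
raw unit-size coordinates retain a genuine 31st dimension of variance of
order ρ² (ρ = Procrustes distance to the consensus). With scaling on, GPA
therefore finishes by rescaling each configuration onto the tangent
hyperplane {X : ⟨X, consensus⟩ = 1}. This replaces the spherical constraint
with a linear one: the aligned set spans an exactly 30-dimensional affine
subspace (34 coordinates − 2 translations − 1 rotation − 1 scale), PCA
reconstruction is exact, and no spurious curvature mode appears. The cost
is that aligned centroid sizes equal 1/cos ρ rather than exactly 1 — a
second-order deviation (≤ ~5% at the default study conditions, zero for
identical shapes). This is the tangent-coordinates construction standard in
geometric morphometrics, applied as a finishing step so the iteration
itself keeps its monotonicity guarantee.

After alignment the rotational frame is arbitrary; for reproducibility the
whole set is rotated so the consensus petiole→midvein-tip axis points along
+y and, when reflection was allowed (so input chirality carries no
information), reflected to a fixed consensus chirality. GPA output is then
invariant, coordinate-by-coordinate, to arbitrary per-leaf similarity
transforms and reflections of the input.

## Morphospace

PCA is computed on the covariance (divisor n−1) of the flattened
(x1,y1,…,x17,y17) aligned coordinates — covariance, not correlation,
because all coordinates share units. Eigenvalues below 1e-12 of the largest
are reported as exactly zero (the similarity null space). Axis signs are
fixed by making each axis's largest-magnitude loading positive, so
eigenleaves are reproducible across runs and platforms; the sign itself is
meaningless. An eigenleaf at k·SD along axis j is
`mean + k·sqrt(λ_j)·axis_j`, unflattened to 17 landmarks; new collections
aligned in the same frame are projected onto the existing axes without
refitting.

## Latent-shape discriminants

Because aligned coordinates are rank-deficient, LDA first reduces to the
PCA sub-basis with eigenvalue > `rank_tol` (1e-8) × the largest, then fits
the Gaussian equal-covariance discriminant there: class means, pooled
within-class covariance (divisor n−g) with a ridge guard of
1e-8 · trace/dim, and priors either class-frequency proportional (default)
or uniform. Posteriors are computed from the log-discriminants with the
shared quadratic term cancelled; ties in the argmax break to the first
class in model order, deterministically. Stage and leaf-number classes are
treated as unordered categories — ordinality enters only through the
apparent − actual arithmetic afterwards.

Cross-collection staging (`cross_stage`) restricts the training collection
to a node window (default S1–S10 / L1–L10), runs one joint GPA over
training + test leaves (so both collections share a frame; a
project-into-train mode exists as an option), fits the discriminants on the
training rows with integer node values as classes, and returns apparent
integer values for the test rows. Training classes with fewer than two
leaves are dropped with a warning.

In-sample reclassification accuracy is optimistically biased (Θ(1/√n); at
n = 200 in 2 dimensions the null training accuracy is ≈ 0.53, identically
for an independent reference implementation). Null-behavior checks in the
test suite therefore measure reallocation accuracy on a held-out draw from
the same null, which is at chance by construction.

## Heterochrony

Relative developmental stage and relative leaf number are
`apparent − actual`, in signed nodes: an S5 leaf staged S7 is +2, an L4
leaf staged L2 is −2. Vine means are arithmetic means of the vine's
per-leaf relatives; species are tested against zero with a one-sample
two-tailed t-test on vine means (exact t distribution — vine counts are
small), requiring ≥ 3 vines and nonzero variance, otherwise a reason code
is reported instead of a statistic. Raw p-values are always reported;
BH-adjusted values can be added side by side. The first tendril node is
indexed from the shoot base (the heteroblastic frame: tendrils appear at
basal nodes earlier in precociously adult vines); nodes bearing no organ
(N) are simply non-tendril, and unknown organ codes are excluded from the
scan with a warning. The tendril correlation is Spearman's rho over vines
with both a staged mean and a tendril, requiring ≥ 4 complete pairs.

**Window-edge censoring.** Apparent values cannot leave the trained
window: a leaf whose effective position is beyond L10 is staged at most
L10. Averaged over the whole window this caps the recoverable shift (a +2
shift reads at most 1.7 on L1–L10 even with a perfect classifier). The
recovery protocol therefore reads the mean relative value off the interior
of the window, with a margin equal to the largest shift the study probes
(2 nodes → L3–L8). The margin is part of the protocol, fixed a priori.

## The synthetic generator

Each vine is one shoot of T_v leaves (Poisson around `mean_total_leaves`,
floored at 10 so the S1–S10/L1–L10 windows are always populated; a
fixed-length mode exists for perfectly anti-indexed shoots). The noiseless
flattened shape of the leaf at node ℓ (Sn = T_v + 1 − ℓ) is

    template + A_s + c_S · exp(−(Sn−1)/τ_S) · u
             + c_L · (1 − exp(−(L_eff−1)/τ_L)) · w,   L_eff = ℓ + δ_v

with u ⟂ w unit directions orthogonal to every species effect A_s (drawn
once per `effect_seed`, so matched train/test collections can share one
generative model), δ_v ~ N(0, `heterochrony_sd`) plus an optional fixed
per-species shift. Saturating exponentials put the strongest ontogenetic
change at the shoot tip and the strongest heteroblastic change near the
base; τ_S = τ_L = 3 nodes. Landmark noise is i.i.d. Gaussian per
coordinate, and each raw configuration is placed arbitrarily (rotation,
translation, log-uniform scale 0.5–2, reflection with probability ½).

The organ series follows the grapevine pattern: every third node bears
nothing; below the tendril onset node t_v the remaining nodes carry flower
clusters, at and above it tendrils, with
t_v = clamp(round(`tendril_base` − γ·δ_v + N(0,1)), 1, T_v). γ > 0 couples
precocious heteroblasty to earlier tendrils; the observed first tendril
node (what a field scan would record) is stored in the truth alongside the
generative t_v.

Default study conditions: 3 species × 20 vines, ~25 leaves per shoot
(~1500 leaves), species/stage/leaf-number effect scales 0.15/0.25/0.25 in
units of the unit-size template, heterochrony SD 1 node, landmark noise SD
0.01 (≈1% of leaf size, a plausible digitization error). For the
shift-recovery studies the noise is set to a quarter of the *node-level*
effect step (the mean adjacent-node shape displacement inside the staging
window, ≈0.0066 at the defaults). The node step, not the full trajectory
amplitude, is the relevant scale: the heterochrony analysis operates at
single-node resolution, and noise at a quarter of the full amplitude would
make adjacent node classes statistically indistinguishable by
construction, so no staging method could resolve a shift. The
tendril-coupling detection study uses γ = 2, at which the population
correlation survives the attenuation from the unit node noise, integer
rounding and the every-third-node organ skip.

What the generator does *not* emulate: allometric within-leaf expansion
beyond the single latent direction, venation or area, asymmetry,
measurement error correlated across landmarks, or species-by-development
interactions (the latent subspaces are exactly orthogonal unless the
`confounded` mode is enabled). Passing recovery tests therefore show the
pipeline is correct and well-calibrated under additive latent-trajectory
structure — not that real leaves satisfy that structure.

With fixed shoot lengths, relative Sn and relative Ln are strongly
anti-correlated across vines (the two indices count the same nodes from
opposite ends, and the stage classifier's class means absorb the
heteroblastic channel). With variable shoot lengths the anti-correlation
weakens markedly — shoot-length variability moves both relative values
through the trajectory slopes in the same direction — which is the
decoupling the complementary Sn/Ln indexing is designed to exploit; the
suite tests the strong fixed-length anti-correlation and the strict
weakening under variable lengths.

## Statistics utilities

* **Spearman's rho**: Pearson correlation of midranks. Two-tailed p by
  exact enumeration of the permutation null for n ≤ 8, and by the
  t approximation t = ρ√((n−2)/(1−ρ²)) above. Rho is defined from 3
  complete pairs; procedures that feed on it (tendril correlation,
  correlation matrices) require ≥ 4.
* **Kruskal–Wallis**: tie-corrected H with df = g−1 and the chi-square
  tail; all-tied data are rejected as undefined.
* **Benjamini–Hochberg**: step-up q_(i) = min_{j≥i} p_(j)·m/j, capped at
  1, returned in input order; never below the raw p, never above
  Bonferroni, order-preserving.
* **Correlation matrices**: Spearman on pairwise-complete observations per
  column pair; pairs with < 4 complete rows (or constant values) are
  reported missing rather than fatal; BH is applied jointly across the
  defined off-diagonal upper-triangle p-values; an n matrix records the
  rows used per cell.
* **Hierarchical clustering**: agglomeration on d = 1 − r (the plain
  correlation distance; √(2(1−r)) and 1 − |r| were considered and
  rejected as further from "distance from correlation"), r Spearman by
  default for consistency with the correlation matrices, Pearson
  optional; complete linkage by default, average and single available.
  Exact distance ties (possible with rank-based r, whose values are
  rationals) are resolved by the linkage implementation's deterministic
  scan order; tie resolution affects topology only where the data
  genuinely do not prefer one merge. Dendrograms serialize to newick with
  branch length = parent merge height − child merge height (leaves at
  height 0), labels quoted when they contain metacharacters.

## Numerical and interface choices

* Reflection and unit-size scaling are on by default in GPA; original
  centroid sizes are kept alongside the aligned shapes so size analyses
  remain possible.
* Flattening order everywhere is (x1, y1, …, x17, y17).
* Wide CSV is the canonical table dialect
  (`leaf_id,vine_id,species,stage,leaf_number,organ_opposite,x1,y1,…`);
  long CSV is supported both ways; TPS (`LM=17` blocks keyed by `ID=`,
  with a metadata sidecar CSV) is read-only convenience. Coordinates are
  written at full precision and read back with round-trip float parsing,
  so write∘read is the identity.
* The per-vine consistency rules (unique Sn, unique Ln, Sn + Ln constant)
  are enforced strictly by default with a lenient warning mode, because
  real field collections can violate them (tip leaves too small to
  flatten); synthetic data satisfy them by construction.
* Midshoot subsetting keeps, per vine, the n leaves whose Ln is closest to
  (total+1)/2, ties broken toward the shoot base — deterministic.
* CLI manifests echo the subcommand, parameters, seed and package/numpy
  versions, and deliberately contain no timestamps, so a rerun from the
  same manifest reproduces artifacts bit for bit.

## Known limitations

* No sliding semilandmarks, thin-plate splines, or 3D configurations.
* No mixed-effects modeling of the vine/species nesting; the two-stage
  averaging (leaf → vine → species) is the contract.
* Tangent-plane scaling trades exact unit centroid size for exact
  30-dimensional rank (see above); analyses that require sizes exactly 1
  should use the stored `centroid_sizes`.
* The exact-permutation Spearman p enumerates n! orderings and is capped
  at n = 8 by design.
* Whether real collections' variance fractions should be computed on raw
  or tangent-projected coordinates is a genuine modeling choice; this
  package documents and uses the tangent-plane coordinates its GPA
  produces.
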