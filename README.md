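# latentleaf

Landmark-based morphometrics of grapevine (*Vitis*) leaf shape: generalized
Procrustes alignment, eigenleaf morphospaces, linear-discriminant "latent
shapes" for species identity and developmental context, and heterochrony
statistics — with a synthetic shoot generator that provides ground truth for
every stage of the analysis.

## The problem

A single leaf's shape is a composite of several biological signals: which
species it belongs to, how far along its own expansion it is (developmental
stage **Sn**, counted from the shoot tip, S1 = youngest measurable leaf),
and where on the shoot it was initiated (leaf number **Ln**, counted from
the base — the heteroblastic series of the maturing shoot apex). Because Sn
and Ln count the same nodes from opposite ends of one shoot, Sn + Ln is
constant within a vine; variability in shoot length is what makes the two
partially separable across vines.

`latentleaf` is for researchers who digitize leaves as ordered landmarks
(here the 17-landmark grape scheme: petiolar junction, midvein tip, sinus
and lobe tips, vein termini and branch points) and want to ask: *are the
shape signatures of genetics and development separable, and do species
differ in developmental timing?*

## The method

1. **Generalized Procrustes analysis (GPA).** Configurations X_i of 17
   landmarks are superimposed by removing translation, scale, rotation and
   (optionally, on by default) reflection; the optimal rotation comes from
   the SVD of the cross-covariance of centered, unit-centroid-size
   configurations, iterated against a consensus mean shape. Alignment
   finishes on the tangent hyperplane at the consensus, so the aligned
   coordinates span exactly 34 − 4 = 30 dimensions.
2. **Shape PCA.** Eigendecomposition of the covariance of the flattened
   aligned coordinates gives "eigenleaves": orthogonal modes of shape
   variation, visualizable at ± k·SD about the mean leaf.
3. **Latent shapes (LDA).** Linear discriminant analysis on the aligned
   coordinates isolates the multivariate signature separating one factor
   (species, Sn, or Ln) independent of the others; reallocating each leaf
   to its *apparent* class yields actual-vs-apparent confusion matrices,
   and a reference collection can be used to stage leaves from another.
4. **Heterochrony.** Per leaf, `relative value = apparent − actual` (in
   nodes); per-vine means are tested per species against zero with a
   one-sample two-tailed t-test, and correlated with the first tendril
   node (the basal-most node whose opposite organ is a tendril rather than
   a flower cluster) using Spearman's rho.
5. **Statistics utilities.** Spearman's rho (midranks; exact permutation
   p for n ≤ 8), Kruskal–Wallis, Benjamini–Hochberg FDR, pairwise-complete
   correlation matrices, and 1 − r correlation-distance hierarchical
   clustering with newick export.

The synthetic generator builds shoots whose leaves follow species effects
plus saturating ontogenetic (Sn) and heteroblastic (Ln) latent trajectories
in orthogonal shape subspaces, with vine-level heterochronic shifts δ_v
coupled to the tendril onset node — so every downstream claim is testable
against known truth.

## Worked example

```python
from latentleaf import (SyntheticConfig, generate, gpa, fit_pca, fit_lda,
                        predict_classes, confusion, cross_stage, build_report,
                        select_positions)

config = SyntheticConfig(seed=1, n_species=3, vines_per_species=20)
dataset, truth = generate(config)
aligned = gpa(dataset)                       # Procrustes superimposition
space = fit_pca(aligned)                     # eigenleaf morphospace

labels = [r.species for r in dataset]
model = fit_lda(aligned, labels)             # species latent shape
apparent, _ = predict_classes(model, aligned)
cm = confusion(labels, apparent, labels=model.class_labels)

windowed = select_positions(dataset, "leafnum_window", lo=3, hi=8)
staged = cross_stage(dataset, windowed, target_kind="leaf_number", window=(1, 10))
report = build_report(dataset, staged)       # heterochrony statistics
```

This prints (via the obvious `print` statements):

```
simulated 1530 leaves from 60 vines
GPA converged in 6 iterations (final consensus change 5.74e-12)
variance explained: PC1 41.0%, PC2 22.0%, PC3 16.6%, PC4 10.3%
species reclassification accuracy: 1.000
   species  mean_of_vine_means  t_statistic  p_value
species_01               0.275        1.713    0.103
species_02               0.192        0.961    0.349
species_03               0.217        1.622    0.121
tendril-node correlation: rho = -0.34, p = 0.0086 over 60 vines
```

Reading the numbers: the first four eigenleaves carry ~90% of shape
variance; species are perfectly separable at the default effect scales; the
per-species mean relative leaf numbers sit near zero (no shift was
injected, so the t-tests are properly non-significant), while the negative
tendril correlation reflects the generator's built-in coupling between a
vine's heterochronic shift and its tendril onset node.

The same pipeline is scriptable from a shell:

```sh
latentleaf simulate --seed 1 --out run/sim
latentleaf gpa --input run/sim/leaves.csv --out run/gpa
latentleaf pca --input run/gpa/aligned.csv --out run/pca
latentleaf lda --input run/gpa/aligned.csv --target species --out run/lda
latentleaf stage --train run/sim/leaves.csv --test run/sim/leaves.csv \
    --target leaf_number --window 1 10 --window-test --out run/stage
latentleaf heterochrony --input run/sim/leaves.csv \
    --predictions run/stage/apparent.csv --out run/het
```

Each stage writes its CSV/JSON/newick artifacts plus a `manifest.json` from
which the outputs are reproducible bit for bit.

## Layout

| module | contents |
| --- | --- |
| `latentleaf.leafdata` | landmark/leaf/dataset types, wide/long CSV and TPS readers, position subsetting, summaries |
| `latentleaf.procrustes` | centroid size, pairwise superimposition, GPA |
| `latentleaf.morphospace` | shape PCA, projection, eigenleaf reconstruction |
| `latentleaf.discriminant` | LDA latent shapes, reallocation, confusion matrices, cross-collection staging |
| `latentleaf.heterochrony` | relative values, per-vine/species tests, tendril-node correlation |
| `latentleaf.statmethods` | Spearman, Kruskal–Wallis, BH-FDR, correlation matrices, clustering, newick |
| `latentleaf.synthetic` | the shoot generator and its ground truth |
| `latentleaf.cli` | the `latentleaf` command |

See `docs/methods.md` for the model details, parameter meanings and the
numerical design choices.
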