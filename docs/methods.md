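# Methods

This note documents the models, numerical choices and limitations behind
`dermovasc`, in the order the pipeline runs.

## Specimen data

The two packaged tables hold one dermal-plate cross-section per row: a
porosity fraction in [0, 1], a lifestyle category, the sampled anatomical
region, an ornamentation flag, a geological age and a collection number.
Lifestyle vocabularies are dataset-specific — terrestrial / freshwater /
marine for the turtle total group; terrestrial / semi-aquatic for the
crocodylian line, where freshwater and coastal ambush predators are
pooled because their amphibious habit is equivalent for the hypothesis
under test. *Yarasuchus deccanensis* is retained inside the
pseudosuchian table (it was figured and sampled with that dataset) but
tagged `Avemetatarsalia-outgroup`, so `drop_outgroup()` can exclude it;
both inclusion modes are supported because the original analysis does
not state which was used. Sampling units are plates, not species:
multiple sections of one species are distinct records whose
non-independence is handled on the tree (below), not by averaging.

## Porosity measurement

Input is a two-valued raster (bone / void). Digital topology uses the
standard paradox-free pairing: bone 8-connected, void 4-connected. Void
4-connected to the raster border is exterior background; porosity is
enclosed void / (enclosed void + bone). This equals a brute-force
flood-fill count, which the tests verify on random rasters.

Ornamented plates carry apical crests separated by pits that are packed
with vessels; to count pit space as vascular area, crest apices are
joined by one-pixel-wide digital straight segments. Apices are local
maxima of the boundary elevation profile facing a caller-chosen side
(top/bottom/left/right), with two noise filters that the source protocol
leaves unspecified: minimum prominence (default 3 px) and minimum
separation (default 5 px), both configurable. Plateau apices take their
midpoint, ties rounding to the lower index. Consecutive apices are
chained — among order-preserving pairings this minimises total bridged
length, and non-adjacent chords would leave crests outside the hull.
Whether the outermost apices should also connect to the section margin
is genuinely open; the default is *no* (`connect_margins=False`),
because auto-connecting can silently enclose lateral embayments that are
not pits; the flag enables it. Bridging is monotone (porosity never
decreases) and a no-op on unornamented sections, and on equal-height
crests it is idempotent. On unequal crests a second bridging pass after
re-detection could in principle add chords above earlier ones; the
pipeline bridges exactly once.

Grayscale input can be thresholded (`binarize`, dark-bone convention by
default), mirroring a manual segmentation step; the canonical input is
already binary. Raster I/O is single-channel PNG/TIFF, 0 = bone,
255 = void, polarity configurable.

## Trees

Chronograms are rooted trees with branch lengths in Myr, wrapped around
dendropy; fossil tips make them non-ultrametric, and polytomies are
allowed throughout because every statistic here is computed from the
covariance matrix, not from contrasts. Multiple plates of one species
hang from a hypothetical common ancestor 1 Myr above the placeholder
tip (pendant branch shortened by 1, k pendant branches of 1 added);
on trees spanning 180–250 Myr this perturbs total tree length well
under 1%, and it leaves every between-species MRCA age untouched. The
Brownian covariance is C[i,j] = root-to-MRCA path length, built in one
postorder sweep. Pagel's λ multiplies the off-diagonal of C; the upper
bound defaults to 1 (non-ultrametric trees can admit λ > 1, but the
interpretation is fragile and the analyses here stay within [0, 1]).
A λ that breaks positive definiteness raises.

The packaged chronograms for the two empirical datasets are
*reconstructions*: topology follows the accepted relationships of the
sampled taxa, node ages are rough literature-informed values, because
the original calibrated trees were never published numerically. Every
quantity that depends on those branch lengths is therefore illustrative;
the statistical machinery is validated on synthetic trees instead.

## Phylogenetic signal

`gls_mean_mse` computes the GLS phylogenetic mean
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x, the phylogenetic mean squared error
MSE = rᵀC⁻¹r/(n−1) and its raw counterpart MSE0 = rᵀr/(n−1) via Cholesky
solves. Blomberg's K divides the observed MSE0/MSE by its BM
expectation [tr(C) − n/(1ᵀC⁻¹1)]/(n−1); K = 1 exactly when C ∝ I. The
permutation test shuffles trait values across tips and counts permuted
MSE ≤ observed (signal = smaller-than-random phylogenetic error), with
the add-one estimator (1 + hits)/(n_perm + 1) so p is never zero.

Pagel's λ is estimated by profile maximum likelihood: for each λ the
mean and rate have closed forms (â as above, σ̂² = rᵀC(λ)⁻¹r/n), leaving
a 1-D profile log-likelihood that is scanned on a 41-point grid and
refined by bounded Brent search in the best bracket; the combination
stays within 1e-4 of a dense grid even on shallow surfaces, which the
tests check. The p-value is a likelihood-ratio test against λ = 0
(independent tips with depth-proportional variances) on χ²(1) — the
convention of the reference R implementations; a λ = 1 null (pure BM)
is available by flag. A flat likelihood (star tree) returns the lower
bound with a warning. Both K and λ are invariant under affine trait
transforms, and the tests cross-check both statistics against
phytools' `phylosig` and against an independent-contrasts identity.

## Phylogenetic ANOVA

Default mode `bm_simulation`: compute the classical one-way F of the
trait against the groups, estimate the BM rate from the data by GLS
(the F statistic is scale-free, so this only matters for reporting),
simulate the null F distribution from BM vectors on the tree
(Cholesky-factor sampling, vectorised), and take the add-one upper-tail
p. On a star tree this converges to the classical p; under BM with
clade-confounded groups it is properly conservative where the classical
test is anticonservative. Type-I error at α = 0.05 is calibrated to
0.05 ± 0.02 over 500 replicates in the acceptance suite.

Because the source analysis says the phylogenetic correction is
"quantified either by K or λ", two GLS variants are provided:
`gls_lambda` runs the group-means GLS F test under σ²C(λ̂), and
`gls_K_scaled` does the same with the off-diagonal scaled by
min(K̂, 1). The latter is a documented approximation — K is a ratio
statistic, not a covariance transform — and exists for comparability,
not as a recommendation.

Group descriptives use the sample (n−1) standard deviation (the
population form does not reproduce the published cells), midpoint
medians for even groups, full-precision computation with half-up
rounding only at display. One published cell — the semi-aquatic median,
printed 0.19 — is contradicted by a brute-force median of its own 20
raw values (0.175 → 0.18); it is reported as a discrepancy, never
force-matched. Singleton groups report sd = 0 with an explicit
`sd_defined=False` flag.

## Ancestral states

Squared-change parsimony minimises Σ (x_child − x_parent)²/w over
internal states, w = branch length (default) or 1. The normal equations
form a graph-Laplacian system solved exactly (dense; the trees have tens
of nodes), so no iterative tolerance is exposed. The weighted solution
equals the BM maximum-likelihood states; its root equals the GLS
phylogenetic mean, which the tests verify. States obey the maximum
principle (they stay inside the tip range) and transform equivariantly
under affine maps of the trait. The weighted/unweighted switch exists
because the original software's default is ambiguous.

## Synthetic data

The generators define the validation conditions:

- **Trees** — star, near-balanced (node ages halving per split), or a
  pure-birth ("yule-like") process rescaled to a fixed depth; all
  ultrametric by construction, labelled t1..tn, deterministic per seed.
- **Traits** — with λ = 1, exact BM by root-to-tip Gaussian branch
  increments (cheap on large trees); with λ < 1, a joint draw from
  N(root, σ²C(λ)) via Cholesky. Group mean shifts are added at the
  tips. Defaults mirror the shape of the empirical problem: 64 tips,
  200 Myr depth (the two datasets span 180 and 250 Myr), σ² = 5e-5 per
  Myr (tip sd ≈ 0.1, matching the observed porosity spread), root state
  0.15 (mid-range porosity).
- **Sections** — a rectangular bone silhouette inside an exterior void
  frame; pores are rejection-sampled non-overlapping discs (radius ~
  Normal(6, 2) px, clipped ≥ 1) kept ≥ 2 px inside the bone, topped up
  with isolated single pixels so the carved area equals
  round(target × silhouette area) *exactly* — the achieved porosity
  differs from the target only by that one-pixel rounding, far inside
  the documented ±0.01. Ornamented sections add equal-height triangular
  crests (45° flanks) with pits of configurable depth carved between
  the bases; apex coordinates, pore mask and pit mask are recorded, and
  because the apices are level the bridge is a horizontal chord and the
  enclosed-void identity (pores + pits) holds to the pixel.

What the generators do **not** emulate: real histological texture,
irregular plate outlines, segmentation noise, unequal crest heights,
measurement error in lifestyle assignment. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated models, not the field accuracy of porosity segmentation.

## Problem sizes and determinism

Simulation experiments use 64-tip trees with 200–1000 replicates for
signal calibration, 500 replicates × 999 simulations for ANOVA size,
and 50 seeded rasters for the porosity identity — sizes at which the
Monte-Carlo standard errors are comfortably inside the asserted
tolerances. Every stochastic routine takes an explicit seed;
`scripts/acceptance.py` spawns all of its seeds from one `--seed`
argument.

## Known limitations

- Empirical K/λ/ANOVA values depend on the reconstructed fixture
  chronograms and are illustrative only.
- The λ likelihood surface is assumed unimodal enough for
  grid-plus-Brent refinement; pathological multimodality finer than the
  0.025 grid spacing could in principle be missed.
- `gls_K_scaled` is an interpretive approximation (see above).
- Crest bridging assumes the ornamented side is one of the four
  cardinal directions; no automatic side detection.
- Zero-length terminal branches are only perturbed (1e-8 Myr) when they
  make C singular; analyses mixing identical tips at λ = 1 can still be
  ill-conditioned.
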