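# Methods

`mycobeta` implements a mycorrhizal-stratified analysis of latitudinal
gradients in tree beta-diversity for stem-mapped forest plots, exercised on
synthetic data with programmed gradients. This note records the models, the
numerical conventions, and the design choices made where the design was
genuinely open.

## Beta-diversity partition

For a pair of quadrats with species abundance vectors `x1`, `x2`, let

    A = Σ_j min(x1j, x2j)        shared abundance
    B = Σ_j (x1j − min)          abundance unique to quadrat 1
    C = Σ_j (x2j − min)          abundance unique to quadrat 2

The partition is Baselga's abundance-based decomposition of Bray–Curtis
dissimilarity:

    β_total      = (B + C) / (2A + B + C)
    β_turnover   = min(B, C) / (A + min(B, C))        (balanced variation)
    β_nestedness = |B − C| / (2A + B + C) · A / (A + min(B, C))

`β_turnover + β_nestedness = β_total` is an algebraic identity; the test
suite asserts it at 1e−12 on random pairs and checks `β_total` against an
independent Bray–Curtis implementation (`scipy.spatial.distance.braycurtis`).
The all-pairs computation uses the identity `A = (t_i + t_j − d_ij)/2` with
`d_ij` the city-block distance, so one `pdist` call yields every pair.

Degenerate conventions (chosen by continuity, logged when used):

* one quadrat empty: `total = 1, turnover = 0, nestedness = 1`;
* both quadrats empty: undefined, raises; the pairing stage excludes empty
  quadrats and a sampled replicate containing one is redrawn.

## Sampling protocol

Plots are tiled from the origin into half-open square quadrats
`[k·s, (k+1)·s)`; partial quadrats at the far edges are dropped so all
retained quadrats have equal area. A tree exactly on an internal boundary
belongs to the quadrat it opens (half-open convention; the alternative is
equally defensible, the choice is isolated in `grid_quadrats`). The
protocol samples 30 quadrats at 10 m, 15 at 20 m and 15 at 50 m without
replacement, computes the mean pairwise partition, and repeats 200 times;
quadrat sets may repeat across repetitions. The 95% CI of each replicate
mean is a percentile bootstrap (1000 resamples) over the 200 replicate
values. Plots with fewer complete quadrats than the subsample (or, in
strict mode, area < 8 ha at the 50 m scale) are excluded at that scale.

## Mycorrhizal stratification

Species are assigned AM / EcM / other by a genus-level lookup first, then
family-level; unmapped species fall to "other" with a warning. Taxa recorded
with two or more mycorrhizal types resolve per policy: "other" by default,
or forced to AM or EcM for sensitivity analyses. Non-tree growth forms
(lianas, palms, shrubs) are removed before gridding. Groups analysed:
all, AM, EcM, all−AM, all−EcM; a group empty in a plot is skipped there.

## Gradient models

Beta metrics are proportions, so latitudinal trends are fitted by beta
regression (logit mean link, constant precision φ, maximum likelihood via
`statsmodels` `BetaModel`). Exact 0/1 values are squeezed to 0.005/0.995
first. The covariate is the elevation-adjusted absolute latitude

    adjusted latitude = elevation/111 + |latitude|   [degrees]

treating a 100 m climb as thermally equivalent to ~100 km poleward
(1° ≈ 111 km). Pseudo-R² is the squared Pearson correlation between
`logit(y)` and the fitted linear predictor (the convention of the reference
beta-regression implementation); the slope test is Wald; the confidence
band on the mean is delta-method on the link scale (a bootstrap band would
also be defensible; delta was chosen for determinism and speed). Calibration
at n = 45 plots shows the Wald test rejects at ≈ 0.06 under the null —
the usual mild anti-conservatism of Wald tests at moderate n.

Group contrasts use the two-sided Mann–Whitney U test with
`W = #{(a_i, b_j): a_i > b_j}` (ties ½): exact enumeration when
`n_a + n_b ≤ 20` without ties, tie-corrected normal approximation otherwise.

## Topography and environment

From the four corner elevations of each quadrat (side s): mean elevation is
the corner mean; slope is the mean angular slope of the four planes through
each 3-corner subset (the forest-plot convention); aspect comes from the
least-squares plane's downslope direction, sin-transformed to a sunward
index in [−1, 1] with the sign flipped in the southern hemisphere so +1
always means equatorward-facing (flat quadrats get 0); convexity is focal
mean elevation minus the mean of the up-to-8 adjoining quadrats' means
(edge quadrats use the neighbors that exist). Plot-level summaries are the
mean, range and CV of each of the four variables (12 topographic columns);
a CV whose mean is ~0 (possible for aspect and convexity) is undefined and
set to a sentinel of 0 with a log message. The 22 climatic variables
(19 bioclim + solar radiation + PET + aridity) are consumed as a given
table; the assembled environment table has exactly 34 columns in a fixed
order.

## Driver attribution

**PCNM.** Euclidean distances on raw (longitude, latitude) pairs —
great-circle distance is deliberately not used, matching common practice of
feeding coordinates directly; truncation at the longest minimum-spanning-
tree edge; distances beyond it replaced by 4t; principal-coordinate
analysis (Gower centring) of the modified matrix; axes with positive
eigenvalues returned as principal coordinates (eigenvector × √eigenvalue).

**Forward selection** (of climate-PCA axes and of PCNM axes) uses a
double-stopping design: a permutation test of the global model gates entry,
then candidates are added greedily by R² gain. Two choices depart from the
textbook recipe, both to keep the per-step false-entry rate at α:

* the entry test is a *max-statistic* permutation test — the best
  candidate's gain is compared with the null distribution of the maximum
  gain over all remaining candidates (Freedman–Lane shuffle of current
  residuals). A per-candidate null would admit a spurious variable with
  probability ≈ 1 − (1−α)^p per step.
* the cumulative adjusted-R² ceiling (selection must not exceed the global
  model's adjusted R²) applies from the second candidate on. With
  irrelevant candidates present the global adjusted R² fluctuates around
  the 1-predictor value, so applying the ceiling to the first pick would
  reject a genuinely strong lone predictor about half the time.

Candidate sets are capped at 8 axes (n = 40–45 plots): a large candidate
set dilutes the global permutation gate and erodes residual degrees of
freedom in the joint model.

**Variation partitioning** fits env-only, space-only and joint linear
models and reports pure/shared/residual fractions on the adjusted-R² scale
(they sum to 1 by construction; unadjusted R² values are carried alongside
for transparency). The env-only, space-only and joint fractions get
permutation tests (response-row permutation, p = (exceed + 1)/(n_perm + 1));
the shared fraction is not testable. Negative adjusted fractions are
reported as computed — they are a known feature of the adjusted scale, not
clipped.

**Random forest.** Regression forests (default 500 trees, mtry = ⌊p/3⌋,
bootstrap resampling of plots) via scikit-learn. Importance is the increase
in node purity: the total decrease in residual sum of squares from splits
on the variable, averaged over trees — computed from the tree internals
because scikit-learn only exposes a normalized variant. Significance:
refit the forest on row-permuted responses n_perm times; p is the fraction
of null importances meeting the observed one. Partial dependence is
evaluated on a 25-point grid per predictor by brute-force prediction
averaging.

## Synthetic data generator

The generator emulates a latitudinal network of stem-mapped plots; it is
the test-bed for every stage, not a model of any real forest.

* **Latitudes** evenly spaced over the configured range plus Gaussian
  jitter (0.5°).
* **Species pools** per plot: AM and EcM pool sizes are linear in
  |latitude| (Poisson-rounded, min 1); defaults decline for AM
  (120 − 1.5/°) and stay flat for EcM (25), plus a small fixed "other"
  pool. No field estimate of these slopes exists; the magnitudes are
  placeholders chosen to give one interpretable knob per observed pattern.
* **Abundances**: lognormal species-abundance distribution (σ = 1.5)
  within each mycorrhizal group; group shares set by the (clamped) linear
  AM-fraction trend and a fixed 5% "other" share.
* **Spatial pattern**: Thomas cluster process — Poisson parents
  (0.005 m⁻²), Gaussian offspring dispersal (sd 8 m) reflected at plot
  edges; each parent carries one species so aggregation is conspecific,
  emulating dispersal limitation.
* **Topography**: a sum of 4 random low-frequency cosine waves, amplitude
  budgeted so the surface range never exceeds the configured relief; the
  same seed sampled at any quadrat size gives the same continuous surface.
* **Climate**: the 22 variables are deterministic monotone functions of
  |latitude| (temperature- and moisture-like variables decline at differing
  rates) plus Gaussian noise, giving realistic collinearity.
* **Reproducibility**: one root seed; plot i draws from the child stream
  `SeedSequence(seed, spawn_key=(i,))`, so any plot is reproducible in
  isolation and output is byte-identical across runs.

What the generator does **not** emulate: density-dependent mortality or any
plant–soil-feedback mechanism (gradients are programmed directly through
pool sizes and fractions), temporal dynamics, irregular plot outlines,
habitat associations between species and topography, and climate that
responds to elevation. Passing tests therefore demonstrate that the
*pipeline recovers programmed statistical structure* — not that any
ecological mechanism produces it.

## Rarefaction experiments

To check that a group's gradient is not an artifact of its abundance or
richness, AM and EcM are equalized per plot before recomputation: per
repetition either `min(N_AM, N_EcM)` stems are drawn without replacement
from each group's tree list (equal individuals) or `min(S_AM, S_EcM)`
species are sampled uniformly and the matrix restricted to them (equal
species); metrics are averaged over 200 repetitions with percentile
intervals. The equalization targets and repetition count are this package's
reconstruction of the standard protocol and sit behind configuration so
alternatives can be swapped in. A negative control — AM and EcM generated
exchangeably — yields statistically indistinguishable gradients after
equalization.

## Problem sizes

Simulation-backed checks run at sizes chosen to keep the full suite fast on
a single core while leaving the conclusions unambiguous: the end-to-end
sign-recovery ensemble uses 40 plots of 1 ha at ~2000 stems each (20 seeds);
beta-regression calibration uses 500 replicates; random-forest permutation
checks use 50–100-tree forests with 199 permutations (the default forest
stays at 500 trees); null-uniformity checks use 200 simulations × 199
permutations, vectorized. `scripts/acceptance.py` reruns the whole analysis
at these sizes from a single `--seed`.

## Known limitations

* The Wald slope test is mildly anti-conservative at n ≤ 45; a likelihood-
  ratio or bootstrap test would tighten it.
* PCNM on raw longitude/latitude treats degrees as Euclidean; for plots
  spanning hemispheres a great-circle option would be more faithful.
* The adjusted-R² VPA fractions can be slightly negative; interpretation
  should stay qualitative, as is standard for eigenvector-based predictor
  sets.
* CV of sign-changing topographic variables (aspect, convexity) is
  ill-defined near zero mean; the sentinel convention keeps tables complete
  but those columns carry little information on flat plots.
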