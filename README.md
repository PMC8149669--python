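# mycobeta

Latitudinal gradients of tree beta-diversity, stratified by mycorrhizal
type, for stem-mapped forest plots.

Tropical forests do not just hold more species than temperate ones — the
*variation* of species composition among localities (beta-diversity) also
changes with latitude, and arbuscular-mycorrhizal (AM) and ectomycorrhizal
(EcM) trees are expected to behave differently because their plant–soil
feedbacks differ in sign. `mycobeta` provides the full analysis chain to
test this on stem-map data (tree coordinates, species, DBH per plot), and a
synthetic-data generator with programmed gradients so every stage is
testable without access to real census data.

## The statistics at the core

For a pair of quadrats with abundance vectors `x1, x2`, with
`A = Σ min(x1j, x2j)` the shared abundance and `B, C` the abundances unique
to either quadrat, total beta-diversity (Bray–Curtis dissimilarity) is
partitioned into balanced-variation turnover and abundance-gradient
nestedness:

    β_total      = (B + C) / (2A + B + C)
    β_turnover   = min(B,C) / (A + min(B,C))
    β_nestedness = |B − C| / (2A + B + C) · A / (A + min(B,C))

with `β_turnover + β_nestedness = β_total` exactly. Per plot, group
(all / AM / EcM / all−AM / all−EcM) and quadrat scale (10/20/50 m), the mean
pairwise partition over 30/15/15 randomly sampled quadrats is averaged over
200 repetitions with bootstrap CIs. Latitudinal trends are fitted by beta
regression (logit link) against the elevation-adjusted absolute latitude
`elevation/111 + |latitude|`; drivers are attributed by variation
partitioning (climate/topography PCA axes vs PCNM spatial eigenfunctions)
and random-forest importance with permutation tests. See `docs/methods.md`
for conventions and design choices.

## Worked example

```python
from mycobeta import (SimConfig, generate_metacommunity, grid_quadrats,
                      stratify, replicate_summary, partition_pair)

# the partition of one quadrat pair
print(partition_pair([3, 2, 0], [1, 2, 4]))
# BetaPartition(total=0.5, turnover=0.4, nestedness=0.09999999999999999)

# a 1-ha synthetic plot at 10 degrees latitude, AM-stratified protocol
cfg = SimConfig(n_plots=1, plot_width=100, plot_height=100,
                trees_per_plot_mean=2000, latitude_range=(10, 10), seed=1)
plot = generate_metacommunity(cfg)[0]
matrix = stratify(grid_quadrats(plot.stem_map, 20.0,
                                species_types=plot.species_types), "AM")
s = replicate_summary(matrix, n_quadrats=15, n_reps=200, seed=1)
print(round(s.mean_turnover, 3), [round(v, 3) for v in s.ci_turnover])
# 0.82 [0.816, 0.823]
```

The pair `(3,2,0)` vs `(1,2,4)` shares `A=3` individuals with surpluses
`B=2, C=4`, giving half the abundance in dissimilarity (total 0.5), most of
it balanced replacement (turnover 0.4) and a small abundance-gradient part
(nestedness 0.1). The second block runs the full subsampling protocol on a
simulated tropical plot: mean AM turnover ≈ 0.82 with a tight bootstrap CI.

## Analysis scripts

The numbered drivers under `analysis/` run the study end to end on the
synthetic ensemble (40 plots, 0–60°, declining AM species pool, flat EcM
pool) and write tables under `results/`:

```bash
python analysis/01_simulate.py        # stem maps, climate, topography
python analysis/02_beta_diversity.py  # partition protocol per plot/group/scale
python analysis/03_gradients.py       # beta regressions vs adjusted latitude
python analysis/04_drivers.py         # variation partitioning + random forest
python analysis/05_rarefaction.py     # equal-individuals / equal-species controls
```

With the default seed, `03_gradients.py` prints (among others):

```
turnover vs adjusted latitude,   AM @ 20 m: slope -0.0227 (logit scale), p = 9.9e-06 (significant),     pseudo-R2 = 0.34, n = 40
turnover vs adjusted latitude,  EcM @ 20 m: slope -0.0045 (logit scale), p = 0.43   (not significant),  pseudo-R2 = 0.02, n = 39
```

— the programmed contrast: AM turnover declines toward high latitude while
EcM turnover is flat, and (per `05_rarefaction.py`) the contrast survives
equalizing stem counts and species counts between the groups, so it is not
an artifact of AM trees being more abundant or speciose.

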