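"""Pipeline orchestration and the abundance/richness-controlled rarefaction.

``run_pipeline`` composes the full analysis on a synthetic metacommunity:
simulate plots, filter stems, grid quadrats at the three scales, stratify
by mycorrhizal group, compute replicate-averaged beta partitions, fit
elevation-adjusted latitudinal beta regressions, and (optionally) run the
driver attribution (variation partitioning and random-forest importance).
Plots with fewer complete quadrats than the subsample requires are excluded
at that scale and listed in the manifest.

The rarefaction experiments remove the AM-vs-EcM disparity in abundance or
richness before comparing gradients: per repetition, both groups are
subsampled to the smaller group's stem count (equal individuals) or species
count (equal species), re-gridded, and the beta metrics recomputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import beta_partition as bp
from . import community as cm
from . import drivers as dr
from . import environment as env
from . import gradient_models as gm
from .synthetic_data import SimConfig, SyntheticPlot, generate_metacommunity

logger = logging.getLogger(__name__)

METRICS = ("total", "turnover", "nestedness")


@dataclass
class PipelineConfig:
    """End-to-end analysis settings (defaults follow the study protocol)."""

    sim: SimConfig = field(default_factory=SimConfig)
    scales: tuple[float, ...] = (10.0, 20.0, 50.0)
    quadrats_per_scale: tuple[int, ...] = (30, 15, 15)
    n_reps: int = 200
    groups: tuple[str, ...] = cm.GROUPS
    dual_policy: str = "other"
    min_dbh: float = 1.0
    n_boot: int = 1000
    n_perm: int = 999
    rf_trees: int = 500
    do_drivers: bool = True
    min_area_ha: float | None = None  # strict small-plot rule at 50 m, e.g. 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.quadrats_per_scale):
            raise ValueError("quadrats_per_scale must align with scales")
        bad = set(self.groups) - set(cm.GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")


def _coarsen_corner_grid(base_grid: np.ndarray, scale: float, base: float = 10.0) -> np.ndarray:
    step = int(round(scale / base))
    if abs(step * base - scale) > 1e-9:
        raise ValueError(f"scale {scale} not a multiple of the {base} m corner grid")
    ny, nx = base_grid.shape[0] - 1, base_grid.shape[1] - 1
    return base_grid[: (ny // step) * step + 1 : step, : (nx // step) * step + 1 : step]


def plot_beta_summaries(
    plot: SyntheticPlot,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], list[str]]:
    """Replicate-averaged beta metrics for one plot, all groups x scales.

    Returns (rows, exclusion log lines).
    """
    stems = cm.filter_trees(plot.stem_map, config.min_dbh)
    rows, exclusions = [], []
    for scale, n_quad in zip(config.scales, config.quadrats_per_scale):
        if config.min_area_ha is not None and scale >= 50 and plot.metadata.area_ha < config.min_area_ha:
            exclusions.append(f"{plot.metadata.name}@{scale}m: area below {config.min_area_ha} ha")
            continue
        try:
            matrix = cm.grid_quadrats(stems, scale, species_types=plot.species_types)
        except ValueError as e:
            exclusions.append(f"{plot.metadata.name}@{scale}m: {e}")
            continue
        for group in config.groups:
            sub = cm.stratify(matrix, group)
            try:
                s = bp.replicate_summary(
                    sub, n_quad, config.n_reps, rng, n_boot=config.n_boot
                )
            except (bp.InsufficientDataError, bp.ScaleExclusionError) as e:
                exclusions.append(f"{plot.metadata.name}/{group}@{scale}m: {e}")
                continue
            for metric, mean, ci in (
                ("total", s.mean_total, s.ci_total),
                ("turnover", s.mean_turnover, s.ci_turnover),
                ("nestedness", s.mean_nestedness, s.ci_nestedness),
            ):
                rows.append(
                    {
                        "plot": plot.metadata.name,
                        "group": group,
                        "scale": scale,
                        "metric": metric,
                        "mean": mean,
                        "ci_low": ci[0],
                        "ci_high": ci[1],
                        "n_reps": s.n_replicates,
                    }
                )
            rel_t, rel_n = bp.relative_contributions(s)
            for metric, val in (("rel_turnover", rel_t), ("rel_nestedness", rel_n)):
                rows.append(
                    {
                        "plot": plot.metadata.name, "group": group, "scale": scale,
                        "metric": metric, "mean": val,
                        "ci_low": np.nan, "ci_high": np.nan, "n_reps": s.n_replicates,
                    }
                )
    return rows, exclusions


def gradient_fits(
    summaries: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Beta regressions of each metric on adjusted latitude, per group x scale."""
    adj = gm.adjusted_latitude(meta["elevation"], meta["latitude"])
    adj = pd.Series(np.asarray(adj), index=meta.index, name="adjusted_latitude")
    out = []
    for (group, scale, metric), sub in summaries.groupby(["group", "scale", "metric"]):
        sub = sub.set_index("plot")
        y = sub["mean"].astype(float)
        x = adj.reindex(sub.index)
        ok = y.notna() & x.notna()
        if ok.sum() < 5:
            continue
        yv = gm.squeeze_boundaries(np.clip(y[ok].to_numpy(), 0, 1))
        try:
            fit = gm.beta_regression(yv, x[ok].to_numpy())
        except (gm.FitError, ValueError) as e:
            logger.warning("fit failed for %s/%s/%s: %s", group, scale, metric, e)
            continue
        out.append(
            {
                "group": group, "scale": scale, "metric": metric,
                "slope": fit.slope, "slope_se": fit.slope_se, "p": fit.p_slope,
                "pseudo_r2": fit.pseudo_r2, "n": fit.n,
            }
        )
    return pd.DataFrame(out)


def environment_table(
    plots: list[SyntheticPlot], scale: float
) -> pd.DataFrame:
    """Assemble the 34-column environment table at one quadrat scale."""
    climate = pd.DataFrame({p.metadata.name: p.climate for p in plots}).T
    topo = {}
    for p in plots:
        grid = _coarsen_corner_grid(p.corner_elevations, scale)
        tg = env.topography_grid(grid, scale, southern=p.metadata.latitude < 0)
        topo[p.metadata.name] = env.plot_topo_summary(tg)
    return env.assemble_environment(climate, pd.DataFrame(topo).T)


def driver_attribution(
    summaries: pd.DataFrame,
    env_tables: dict[float, pd.DataFrame],
    meta: pd.DataFrame,
    config: PipelineConfig,
    groups: tuple[str, ...] = ("all", "AM", "EcM"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variation partitioning and RF importance per group x scale x metric."""
    coords = meta[["longitude", "latitude"]].to_numpy(dtype=float)
    eig = dr.pcnm(coords)
    space_all = pd.DataFrame(
        eig.vectors, index=meta.index,
        columns=[f"pcnm_{k + 1}" for k in range(eig.vectors.shape[1])],
    )
    vp_rows, imp_rows = [], []
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))
    for scale, env_tab in env_tables.items():
        zenv = (env_tab - env_tab.mean()) / env_tab.std().replace(0, 1.0)
        pca = PCA()
        pcs = pd.DataFrame(
            pca.fit_transform(zenv.to_numpy()), index=env_tab.index,
            columns=[f"pc_{k + 1}" for k in range(min(zenv.shape))],
        )
        for (group, metric), sub in summaries[summaries.scale == scale].groupby(
            ["group", "metric"]
        ):
            if group not in groups or metric not in METRICS:
                continue
            sub = sub.set_index("plot")
            idx = sub.index.intersection(env_tab.index)
            y = sub.loc[idx, "mean"].to_numpy(dtype=float)
            if len(y) < 12:
                continue
            # cap candidate counts: few axes keep the global permutation
            # gate powerful and the joint model keeps residual df
            max_cand = max(min(8, (len(y) - 3) // 2), 1)
            env_sel = dr.forward_select(
                y, pcs.loc[idx].iloc[:, :max_cand], n_perm=config.n_perm,
                seed=rng,
            )
            sp_sel = dr.forward_select(
                y, space_all.loc[idx].iloc[:, :max_cand], n_perm=config.n_perm,
                seed=rng,
            )
            if not env_sel or not sp_sel:
                logger.info(
                    "skipping VPA for %s/%s@%s: empty selection (env=%s, space=%s)",
                    group, metric, scale, env_sel, sp_sel,
                )
            else:
                vp = dr.variation_partition(
                    y, pcs.loc[idx, env_sel], space_all.loc[idx, sp_sel],
                    n_perm=config.n_perm, seed=rng,
                )
                for frac, val, pv in (
                    ("pure_env", vp.pure_env, vp.p_env),
                    ("shared", vp.shared, np.nan),
                    ("pure_space", vp.pure_space, vp.p_space),
                    ("residual", vp.residual, np.nan),
                    ("joint", vp.pure_env + vp.shared + vp.pure_space, vp.p_joint),
                ):
                    vp_rows.append(
                        {
                            "group": group, "scale": scale, "metric": metric,
                            "fraction": frac, "value": val, "p": pv,
                            "n_env": len(env_sel), "n_space": len(sp_sel),
                        }
                    )
            imp = dr.rf_importance(
                y, env_tab.loc[idx], n_trees=config.rf_trees,
                n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)),
                compute_pd=False,
            )
            for var, r in imp.table.iterrows():
                imp_rows.append(
                    {
                        "group": group, "scale": scale, "metric": metric,
                        "variable": var, "importance": r["importance"],
                        "p": r["p"], "rank": int(r["rank"]),
                    }
                )
    return pd.DataFrame(vp_rows), pd.DataFrame(imp_rows)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full analysis; returns a bundle of DataFrames plus manifest.

    With ``out_dir`` set, writes ``plot_summaries.csv``,
    ``gradient_fits.csv``, ``environment_<scale>m.csv``, ``varpart.csv``,
    ``importance.csv`` and ``manifest.json``.
    """
    plots = generate_metacommunity(config.sim)
    meta = pd.DataFrame(
        [asdict(p.metadata) for p in plots]
    ).set_index("name")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    all_rows, exclusions = [], []
    for p in plots:
        rows, excl = plot_beta_summaries(p, config, rng)
        all_rows.extend(rows)
        exclusions.extend(excl)
    summaries = pd.DataFrame(all_rows)

    fits = gradient_fits(summaries, meta)
    env_tables = {s: environment_table(plots, s) for s in config.scales}

    if config.do_drivers:
        varpart, importance = driver_attribution(summaries, env_tables, meta, config)
    else:
        varpart, importance = pd.DataFrame(), pd.DataFrame()

    from . import __version__

    manifest = {
        "mycobeta_version": __version__,
        "seed": config.seed,
        "sim_seed": config.sim.seed,
        "n_plots": len(plots),
        "n_trees_total": int(sum(p.stem_map.n_trees for p in plots)),
        "groups": list(config.groups),
        "scales": list(config.scales),
        "n_reps": config.n_reps,
        "summary_rows": len(summaries),
        "fit_rows": len(fits),
        "exclusions": exclusions,
    }
    bundle = {
        "plots": plots,
        "metadata": meta,
        "summaries": summaries,
        "fits": fits,
        "environment": env_tables,
        "varpart": varpart,
        "importance": importance,
        "manifest": manifest,
    }
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out / "plot_summaries.csv", index=False)
        fits.to_csv(out / "gradient_fits.csv", index=False)
        for s, tab in env_tables.items():
            tab.to_csv(out / f"environment_{int(s)}m.csv")
        varpart.to_csv(out / "varpart.csv", index=False)
        importance.to_csv(out / "importance.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


# --------------------------------------------------------------------------
# rarefaction experiments

@dataclass
class RarefactionResult:
    """Equalized AM/EcM beta metrics for one plot x scale."""

    target_n: int                 # individuals or species per group
    unit: str                     # "individuals" | "species"
    n_reps: int
    means: pd.DataFrame           # index group, columns METRICS
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame


def _summarize_reps(reps: dict[str, np.ndarray], target: int, unit: str, n_reps: int) -> RarefactionResult:
    means, lo, hi = {}, {}, {}
    for g, arr in reps.items():
        means[g] = arr.mean(axis=0)
        lo[g] = np.percentile(arr, 2.5, axis=0)
        hi[g] = np.percentile(arr, 97.5, axis=0)
    mk = lambda d: pd.DataFrame(d, index=METRICS).T
    return RarefactionResult(target, unit, n_reps, mk(means), mk(lo), mk(hi))


def rarefy_equal_individuals(
    stem_map: cm.StemMap,
    species_types: pd.Series,
    scale: float,
    n_quadrats: int,
    seed: np.random.Generator | int | None = 0,
    n_reps: int = 200,
) -> RarefactionResult:
    """Beta metrics of AM and EcM after equalizing stem counts.

    Per repetition, draw ``min(N_AM, N_EcM)`` stems without replacement from
    each group's tree list, re-grid at ``scale``, sample ``n_quadrats``
    quadrats, and compute the mean pairwise partition. Results are averaged
    over repetitions with percentile intervals.
    """
    rng = np.random.default_rng(seed)
    trees = stem_map.trees
    types = trees.species.map(species_types)
    groups = {g: trees.index[types == g].to_numpy() for g in ("AM", "EcM")}
    if min(len(v) for v in groups.values()) == 0:
        raise bp.InsufficientDataError("AM or EcM absent from the plot; skipped")
    target = min(len(v) for v in groups.values())

    reps = {g: np.empty((n_reps, 3)) for g in groups}
    for r in range(n_reps):
        for g, idx in groups.items():
            take = rng.choice(idx, size=target, replace=False)
            sub = cm.StemMap(
                trees.loc[take].reset_index(drop=True),
                stem_map.plot_width, stem_map.plot_height,
            )
            mat = cm.grid_quadrats(sub, scale, species_types=species_types)
            subset = bp.sample_quadrats(mat, n_quadrats, rng)
            nonempty = subset[mat.counts.to_numpy()[subset].sum(axis=1) > 0]
            reps[g][r] = bp.mean_pairwise(mat, nonempty)
    return _summarize_reps(reps, target, "individuals", n_reps)


def rarefy_equal_species(
    matrix: cm.CommunityMatrix,
    n_quadrats: int,
    seed: np.random.Generator | int | None = 0,
    n_reps: int = 200,
) -> RarefactionResult:
    """Beta metrics of AM and EcM after equalizing species richness.

    Per repetition, sample ``min(S_AM, S_EcM)`` species uniformly from each
    group, restrict the community matrix to them, sample ``n_quadrats``
    quadrats and compute the mean pairwise partition.
    """
    rng = np.random.default_rng(seed)
    types = matrix.species_types
    pools = {g: list(types.index[types == g]) for g in ("AM", "EcM")}
    if min(len(v) for v in pools.values()) == 0:
        raise bp.InsufficientDataError("AM or EcM absent from the plot; skipped")
    target = min(len(v) for v in pools.values())

    reps = {g: np.empty((n_reps, 3)) for g in pools}
    for r in range(n_reps):
        for g, pool in pools.items():
            take = list(rng.choice(pool, size=target, replace=False))
            sub = cm.CommunityMatrix(
                matrix.counts[take], matrix.origins, matrix.scale, types.loc[take]
            )
            subset = bp.sample_quadrats(sub, n_quadrats, rng)
            nonempty = subset[sub.counts.to_numpy()[subset].sum(axis=1) > 0]
            reps[g][r] = bp.mean_pairwise(sub, nonempty)
    return _summarize_reps(reps, target, "species", n_reps)
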