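"""Pipeline orchestration and rarefaction-equalization experiments."""

import numpy as np
import pandas as pd
import pytest

from mycobeta.beta_partition import InsufficientDataError
from mycobeta.community import grid_quadrats
from mycobeta.experiments import (
    PipelineConfig,
    plot_beta_summaries,
    rarefy_equal_individuals,
    rarefy_equal_species,
    run_pipeline,
)
from mycobeta.synthetic_data import SimConfig, generate_metacommunity


def tiny_pipeline_config(seed: int = 0, **kw) -> PipelineConfig:
    base = dict(
        sim=SimConfig(
            n_plots=8, plot_width=120.0, plot_height=100.0,
            trees_per_plot_mean=1200.0, seed=seed,
        ),
        scales=(10.0, 20.0),
        quadrats_per_scale=(20, 15),
        n_reps=15,
        n_boot=100,
        n_perm=49,
        rf_trees=30,
        do_drivers=False,
        seed=seed,
    )
    base.update(kw)
    return PipelineConfig(**base)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    return run_pipeline(tiny_pipeline_config(), out_dir=out), out


class TestRunPipeline:
    def test_bookkeeping_complete(self, bundle):
        b, out = bundle
        man = b["manifest"]
        assert man["n_plots"] == 8
        # 8 plots x 5 groups x 2 scales x 5 metric rows, minus exclusions
        n_excluded = len(man["exclusions"])
        assert man["summary_rows"] + 5 * n_excluded >= 8 * 5 * 2 * 5
        assert (out / "manifest.json").exists()
        assert (out / "plot_summaries.csv").exists()

    def test_rerun_is_byte_identical(self, bundle, tmp_path):
        _, out1 = bundle
        run_pipeline(tiny_pipeline_config(), out_dir=tmp_path)
        for name in ("plot_summaries.csv", "gradient_fits.csv", "environment_20m.csv"):
            assert (tmp_path / name).read_bytes() == (out1 / name).read_bytes()

    def test_environment_tables_complete(self, bundle):
        b, _ = bundle
        for scale, tab in b["environment"].items():
            assert tab.shape == (8, 34)
            assert not tab.isna().any().any()

    def test_metric_means_in_unit_interval(self, bundle):
        b, _ = bundle
        s = b["summaries"]
        core = s[s.metric.isin(["total", "turnover", "nestedness"])]
        assert core["mean"].between(0, 1).all()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="align"):
            tiny_pipeline_config(scales=(10.0,), quadrats_per_scale=(10, 5))
        with pytest.raises(ValueError, match="unknown group"):
            tiny_pipeline_config(groups=("all", "EM"))


class TestSmallPlotExclusion:
    def test_area_rule_excludes_at_coarse_scale(self):
        cfg = tiny_pipeline_config(
            scales=(10.0, 50.0), quadrats_per_scale=(20, 4), min_area_ha=8.0,
        )
        plots = generate_metacommunity(cfg.sim)
        rng = np.random.default_rng(0)
        rows, excl = plot_beta_summaries(plots[0], cfg, rng)
        # 1.2 ha plot: everything at 50 m excluded by the strict area rule
        assert all(r["scale"] == 10.0 for r in rows)
        assert any("area below" in e for e in excl)

    def test_quadrat_count_rule(self):
        cfg = tiny_pipeline_config(
            scales=(20.0,), quadrats_per_scale=(100,), min_area_ha=None,
        )
        plots = generate_metacommunity(cfg.sim)
        rows, excl = plot_beta_summaries(plots[0], cfg, np.random.default_rng(0))
        assert rows == []
        assert len(excl) >= 1


class TestRarefyEqualIndividuals:
    @pytest.fixture(scope="class")
    def plot(self):
        cfg = SimConfig(
            n_plots=1, plot_width=100.0, plot_height=100.0,
            trees_per_plot_mean=2500.0, latitude_range=(10.0, 10.0),
            am_fraction_intercept=0.7, am_fraction_slope=0.0, seed=42,
        )
        return generate_metacommunity(cfg)[0]

    def test_min_rule_and_reproducibility(self, plot):
        t = plot.stem_map.trees
        counts = t.species.map(plot.species_types).value_counts()
        expected = int(min(counts["AM"], counts["EcM"]))
        r1 = rarefy_equal_individuals(
            plot.stem_map, plot.species_types, 20.0, 10, seed=1, n_reps=5
        )
        r2 = rarefy_equal_individuals(
            plot.stem_map, plot.species_types, 20.0, 10, seed=1, n_reps=5
        )
        assert r1.target_n == expected
        assert r1.unit == "individuals"
        pd.testing.assert_frame_equal(r1.means, r2.means)

    def test_metrics_within_unit_interval(self, plot):
        r = rarefy_equal_individuals(
            plot.stem_map, plot.species_types, 20.0, 10, seed=2, n_reps=8
        )
        assert ((r.means >= 0) & (r.means <= 1)).all().all()
        assert (r.ci_low.to_numpy() <= r.ci_high.to_numpy()).all()

    def test_missing_group_raises(self, plot):
        am_only = plot.stem_map.trees[
            plot.stem_map.trees.species.map(plot.species_types) == "AM"
        ].reset_index(drop=True)
        from mycobeta.community import StemMap

        sm = StemMap(am_only, 100.0, 100.0)
        with pytest.raises(InsufficientDataError):
            rarefy_equal_individuals(sm, plot.species_types, 20.0, 10, seed=0, n_reps=2)


class TestRarefyEqualSpecies:
    @pytest.fixture(scope="class")
    def matrix(self):
        cfg = SimConfig(
            n_plots=1, plot_width=100.0, plot_height=100.0,
            trees_per_plot_mean=2500.0, latitude_range=(5.0, 5.0), seed=7,
        )
        p = generate_metacommunity(cfg)[0]
        return grid_quadrats(p.stem_map, 20.0, species_types=p.species_types)

    def test_species_min_rule(self, matrix):
        s_am = (matrix.species_types == "AM").sum()
        s_ecm = (matrix.species_types == "EcM").sum()
        r = rarefy_equal_species(matrix, 10, seed=3, n_reps=5)
        assert r.target_n == min(s_am, s_ecm)
        assert r.unit == "species"

    def test_full_richness_identity(self, matrix):
        # equal pools: sampling s = S returns the unrarefied assemblage
        from mycobeta import beta_partition as bp
        from mycobeta.community import stratify

        types = matrix.species_types
        am_cols = list(types.index[types == "AM"])
        ecm_cols = list(types.index[types == "EcM"])
        k = min(len(am_cols), len(ecm_cols))
        import mycobeta.community as cm

        trimmed = cm.CommunityMatrix(
            matrix.counts[am_cols[:k] + ecm_cols[:k]], matrix.origins,
            matrix.scale, types.loc[am_cols[:k] + ecm_cols[:k]],
        )
        n_q = trimmed.n_quadrats
        r = rarefy_equal_species(trimmed, n_q, seed=0, n_reps=3)
        for g, cols in (("AM", am_cols[:k]), ("EcM", ecm_cols[:k])):
            sub = cm.CommunityMatrix(
                trimmed.counts[cols], trimmed.origins, trimmed.scale, types.loc[cols]
            )
            nonempty = np.flatnonzero(sub.counts.sum(axis=1) > 0)
            direct = bp.mean_pairwise(sub, nonempty)
            np.testing.assert_allclose(r.means.loc[g], list(direct), atol=1e-12)

    def test_expectation_stable_as_reps_double(self, matrix):
        r1 = rarefy_equal_species(matrix, 10, seed=5, n_reps=30)
        r2 = rarefy_equal_species(matrix, 10, seed=6, n_reps=60)
        assert np.allclose(
            r1.means.loc["AM", "total"], r2.means.loc["AM", "total"], atol=0.05
        )


class TestExchangeableNegativeControl:
    def test_equalized_groups_have_indistinguishable_gradients(self):
        # AM and EcM generated exchangeably: rarefied slopes should not
        # differ (two-sided test over seeds)
        from mycobeta.gradient_models import mann_whitney_u

        am_slopes, ecm_slopes = [], []
        for seed in range(6):
            cfg = SimConfig(
                n_plots=10, plot_width=100.0, plot_height=100.0,
                trees_per_plot_mean=1500.0, latitude_range=(0.0, 60.0),
                am_pool_intercept=40.0, am_pool_slope=0.0,
                ecm_pool_intercept=40.0, ecm_pool_slope=0.0,
                am_fraction_intercept=0.475, am_fraction_slope=0.0,
                other_fraction=0.05, seed=900 + seed,
            )
            plots = generate_metacommunity(cfg)
            lat, am, ecm = [], [], []
            for p in plots:
                r = rarefy_equal_individuals(
                    p.stem_map, p.species_types, 20.0, 10, seed=seed, n_reps=10
                )
                lat.append(abs(p.metadata.latitude))
                am.append(r.means.loc["AM", "turnover"])
                ecm.append(r.means.loc["EcM", "turnover"])
            am_fit = np.polyfit(lat, am, 1)[0]
            ecm_fit = np.polyfit(lat, ecm, 1)[0]
            am_slopes.append(am_fit)
            ecm_slopes.append(ecm_fit)
        _, p = mann_whitney_u(am_slopes, ecm_slopes)
        assert p > 0.05
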