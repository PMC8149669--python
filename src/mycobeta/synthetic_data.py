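"""Synthetic stem-mapped forest plots along a latitudinal gradient.

The generator emulates the structure of a network of large forest-dynamics
plots spanning tropical to boreal latitudes: per plot, a stem map produced
by a Thomas cluster process (dispersal-limited conspecific aggregation), a
lognormal species-abundance distribution over a plot-specific species pool,
mycorrhizal labels (AM / EcM / other), a smooth topographic surface sampled
at quadrat corners, and a 22-variable climate vector that declines
deterministically with absolute latitude plus noise.

Latitudinal structure is programmed through four linear-in-|latitude| knobs:
AM and EcM species-pool sizes and the AM fraction of individuals. Defaults
encode the observed contrast — AM richness and prevalence decline toward
high latitude while the EcM pool is flat — with magnitudes chosen as
plausible placeholders, since no quantitative slope is available to copy.

Reproducibility: one root seed; plot ``i`` uses the child stream
``SeedSequence(seed, spawn_key=(i,))`` so each plot is independently
reproducible regardless of how many plots are generated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import PlotMetadata, StemMap

logger = logging.getLogger(__name__)

#: Canonical climate column order: 19 bioclim variables, solar radiation,
#: potential evapotranspiration, aridity index.
CLIMATE_VARS = [f"bio_{i:02d}" for i in range(1, 20)] + ["srad", "pet", "aridity"]

# (value at the equator, change per degree |latitude|, noise scale) for each
# climate variable; slopes make temperature- and moisture-like variables
# decline with |latitude| at differing rates so the set is collinear the way
# real bioclim layers are.
_CLIMATE_PROFILE: dict[str, tuple[float, float, float]] = {
    "bio_01": (27.0, -0.45, 1.0),    # annual mean temperature, degC
    "bio_02": (9.0, 0.05, 0.5),      # mean diurnal range
    "bio_03": (85.0, -0.9, 2.0),     # isothermality
    "bio_04": (500.0, 150.0, 100.0), # temperature seasonality
    "bio_05": (33.0, -0.2, 1.0),     # max temp warmest month
    "bio_06": (21.0, -0.75, 1.5),    # min temp coldest month
    "bio_07": (12.0, 0.55, 1.0),     # annual temp range
    "bio_08": (26.5, -0.35, 1.0),    # mean temp wettest quarter
    "bio_09": (26.0, -0.55, 1.0),    # mean temp driest quarter
    "bio_10": (27.5, -0.25, 1.0),    # mean temp warmest quarter
    "bio_11": (26.0, -0.65, 1.0),    # mean temp coldest quarter
    "bio_12": (2600.0, -30.0, 120.0),# annual precipitation, mm
    "bio_13": (350.0, -3.5, 20.0),   # precip wettest month
    "bio_14": (60.0, -0.8, 8.0),     # precip driest month
    "bio_15": (55.0, 0.3, 5.0),      # precip seasonality
    "bio_16": (950.0, -10.0, 50.0),  # precip wettest quarter
    "bio_17": (220.0, -3.0, 20.0),   # precip driest quarter
    "bio_18": (800.0, -8.5, 50.0),   # precip warmest quarter
    "bio_19": (500.0, -6.0, 40.0),   # precip coldest quarter
    "srad": (17000.0, -90.0, 500.0), # solar radiation, kJ m-2 day-1
    "pet": (1700.0, -16.0, 60.0),    # potential evapotranspiration, mm
    "aridity": (1.6, -0.012, 0.08),  # aridity index (P/PET)
}


class ConfigurationError(ValueError):
    """A SimConfig field is non-finite or out of range."""


@dataclass
class SimConfig:
    """Knobs of the synthetic metacommunity.

    Pool sizes and the AM individual fraction are linear in absolute
    latitude: ``pool = intercept + slope * |lat|`` (Poisson-rounded, min 1)
    and ``am_fraction = clip(intercept + slope * |lat|, 0, 1)``. The default
    slopes encode declining AM richness/prevalence and a flat EcM pool; no
    field estimate of these slopes exists, so the magnitudes are documented
    placeholders, not measured values.
    """

    n_plots: int = 45
    plot_width: float = 300.0
    plot_height: float = 300.0
    latitude_range: tuple[float, float] = (-25.0, 61.0)
    trees_per_plot_mean: float = 18000.0  # ~2000 stems/ha at 9 ha
    am_pool_intercept: float = 120.0
    am_pool_slope: float = -1.5    # species per degree |latitude|
    ecm_pool_intercept: float = 25.0
    ecm_pool_slope: float = 0.0
    other_pool_size: int = 8
    am_fraction_intercept: float = 0.85
    am_fraction_slope: float = -0.008  # proportion per degree
    other_fraction: float = 0.05
    cluster_rate: float = 0.005    # Thomas parent points per m^2
    cluster_sd: float = 8.0        # offspring dispersal sd, metres
    abundance_shape: float = 1.5   # lognormal sigma of the SAD
    topo_relief: float = 30.0      # metres
    climate_noise_sd: float = 1.0  # multiplier on per-variable noise scales
    latitude_jitter: float = 0.5   # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_plots": self.n_plots,
            "plot_width": self.plot_width,
            "plot_height": self.plot_height,
            "trees_per_plot_mean": self.trees_per_plot_mean,
            "cluster_rate": self.cluster_rate,
            "cluster_sd": self.cluster_sd,
            "abundance_shape": self.abundance_shape,
        }
        for name, v in positive.items():
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and positive, got {v}")
        for name, v in (
            ("topo_relief", self.topo_relief),
            ("climate_noise_sd", self.climate_noise_sd),
            ("other_fraction", self.other_fraction),
            ("latitude_jitter", self.latitude_jitter),
        ):
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        if self.other_fraction >= 1:
            raise ConfigurationError("other_fraction must be < 1")
        lo, hi = self.latitude_range
        if not (np.isfinite(lo) and np.isfinite(hi)) or not (-90 <= lo <= hi <= 90):
            raise ConfigurationError(f"invalid latitude_range {self.latitude_range}")
        for name in (
            "am_pool_intercept", "am_pool_slope", "ecm_pool_intercept",
            "ecm_pool_slope", "am_fraction_intercept", "am_fraction_slope",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass
class SyntheticPlot:
    """One generated plot: stem map, metadata, topography, climate."""

    stem_map: StemMap
    metadata: PlotMetadata
    corner_elevations: np.ndarray           # 10 m base-resolution grid
    climate: pd.Series                      # the 22 CLIMATE_VARS
    species_types: pd.Series = field(repr=False)  # species -> AM/EcM/other


def _plot_rng(seed: int, plot_index: int) -> np.random.Generator:
    """Child RNG for one plot: ``SeedSequence(seed, spawn_key=(index,))``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(plot_index,)))


def generate_topography(
    plot_dims: tuple[float, float],
    quadrat_size: float,
    relief: float,
    seed: np.random.Generator | int,
    n_terms: int = 4,
) -> np.ndarray:
    """Smooth cosine-basis surface sampled at all quadrat corners.

    The surface is a sum of ``n_terms`` low-frequency cosine waves with
    random orientations and phases; each amplitude is ``relief / (2 *
    n_terms)`` so the surface range is bounded above by ``relief`` (constant
    k = 1 in the range bound). ``relief = 0`` yields a constant grid.

    Returns an array of shape ``(ny + 1, nx + 1)`` where ``nx, ny`` count
    whole quadrats along x and y; the same seed evaluated at different
    quadrat sizes samples the same continuous surface.
    """
    rng = np.random.default_rng(seed)
    width, height = plot_dims
    if quadrat_size <= 0 or quadrat_size > min(width, height):
        raise ConfigurationError("quadrat_size must be positive and fit in the plot")
    nx, ny = int(width // quadrat_size), int(height // quadrat_size)
    xs = np.arange(nx + 1, dtype=float) * quadrat_size
    ys = np.arange(ny + 1, dtype=float) * quadrat_size
    gx, gy = np.meshgrid(xs, ys)

    # frequencies, orientations and phases drawn once per seed, independent
    # of the sampling resolution
    freqs = rng.uniform(0.5, 2.0, n_terms)
    angles = rng.uniform(0, 2 * np.pi, n_terms)
    phases = rng.uniform(0, 2 * np.pi, n_terms)
    scale = max(width, height)
    z = np.zeros_like(gx)
    amp = relief / (2 * n_terms)
    for k in range(n_terms):
        kx = np.cos(angles[k]) * freqs[k] / scale
        ky = np.sin(angles[k]) * freqs[k] / scale
        z += amp * np.cos(2 * np.pi * (kx * gx + ky * gy) + phases[k])
    return z + 100.0  # arbitrary base elevation


def _species_pool(rng, prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(n)]


def _pool_size(intercept: float, slope: float, abslat: float, rng) -> int:
    mean = max(intercept + slope * abslat, 1.0)
    return max(int(rng.poisson(mean)), 1)


def _thomas_positions(
    n: int, width: float, height: float, rate: float, sd: float, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thomas cluster process: returns x, y and each tree's parent index."""
    n_parents = max(int(rng.poisson(rate * width * height)), 1)
    px = rng.uniform(0, width, n_parents)
    py = rng.uniform(0, height, n_parents)
    parent = rng.integers(0, n_parents, n)
    x = px[parent] + rng.normal(0, sd, n)
    y = py[parent] + rng.normal(0, sd, n)
    # reflect at plot edges (repeat in case of large excursions)
    for _ in range(16):
        x = np.where(x < 0, -x, x)
        x = np.where(x >= width, 2 * width - x, x)
        y = np.where(y < 0, -y, y)
        y = np.where(y >= height, 2 * height - y, y)
        if ((x >= 0) & (x < width) & (y >= 0) & (y < height)).all():
            break
    x = np.clip(x, 0, np.nextafter(width, 0))
    y = np.clip(y, 0, np.nextafter(height, 0))
    return x, y, parent


def _generate_plot(config: SimConfig, index: int, latitude: float) -> SyntheticPlot:
    rng = _plot_rng(config.seed, index)

    abslat = abs(latitude)
    n_am = _pool_size(config.am_pool_intercept, config.am_pool_slope, abslat, rng)
    n_ecm = _pool_size(config.ecm_pool_intercept, config.ecm_pool_slope, abslat, rng)
    n_other = max(config.other_pool_size, 1)
    species = (
        _species_pool(rng, f"p{index:02d}_AM", n_am)
        + _species_pool(rng, f"p{index:02d}_EcM", n_ecm)
        + _species_pool(rng, f"p{index:02d}_OT", n_other)
    )
    types = ["AM"] * n_am + ["EcM"] * n_ecm + ["other"] * n_other
    species_types = pd.Series(types, index=species)

    am_frac = float(np.clip(
        config.am_fraction_intercept + config.am_fraction_slope * abslat, 0.0, 1.0
    ))
    p_other = config.other_fraction
    group_p = np.array([am_frac * (1 - p_other), (1 - am_frac) * (1 - p_other), p_other])

    # lognormal SAD within each group, scaled by the group's individual share
    rel = np.exp(rng.normal(0.0, config.abundance_shape, len(species)))
    bounds = np.cumsum([0, n_am, n_ecm, n_other])
    probs = np.empty(len(species))
    for g in range(3):
        seg = slice(bounds[g], bounds[g + 1])
        probs[seg] = group_p[g] * rel[seg] / rel[seg].sum()
    probs /= probs.sum()

    n_trees = int(rng.poisson(config.trees_per_plot_mean))
    x, y, parent = _thomas_positions(
        n_trees, config.plot_width, config.plot_height,
        config.cluster_rate, config.cluster_sd, rng,
    )
    # conspecific aggregation: each Thomas parent carries one species drawn
    # from the SAD; offspring inherit it
    n_parents = parent.max() + 1 if n_trees else 1
    parent_species = rng.choice(len(species), size=n_parents, p=probs)
    sp_idx = parent_species[parent]
    dbh = np.round(1.0 + rng.lognormal(1.0, 0.8, n_trees), 1)

    trees = pd.DataFrame(
        {
            "tree_id": [f"t{index:02d}_{i:06d}" for i in range(n_trees)],
            "x_m": x,
            "y_m": y,
            "species": [species[j] for j in sp_idx],
            "dbh_cm": dbh,
        }
    )
    stem_map = StemMap(trees, config.plot_width, config.plot_height)

    corner = generate_topography(
        (config.plot_width, config.plot_height), 10.0, config.topo_relief,
        np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index, 1))),
    )
    plot_elev = float(np.clip(rng.gamma(1.2, 350.0), 2.0, 3300.0))

    clim = {}
    for var in CLIMATE_VARS:
        base, slope, noise = _CLIMATE_PROFILE[var]
        clim[var] = base + slope * abslat + rng.normal(0, noise * config.climate_noise_sd)
    climate = pd.Series(clim, name=f"plot{index:02d}")

    meta = PlotMetadata(
        name=f"plot{index:02d}",
        latitude=latitude,
        longitude=float(rng.uniform(-180, 180)),
        elevation=plot_elev,
        area_ha=stem_map.area_ha,
    )
    return SyntheticPlot(stem_map, meta, corner, climate, species_types)


def generate_metacommunity(config: SimConfig) -> list[SyntheticPlot]:
    """Generate ``n_plots`` plots at jittered, evenly spaced latitudes.

    Deterministic: an identical config (including seed) reproduces identical
    plots. See the module docstring for the per-plot statistical model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2**20,)))
    lo, hi = config.latitude_range
    lats = np.linspace(lo, hi, config.n_plots)
    lats = np.clip(lats + rng.normal(0, config.latitude_jitter, config.n_plots), -90, 90)
    plots = [_generate_plot(config, i, float(lats[i])) for i in range(config.n_plots)]
    logger.info(
        "generated %d plots, %d trees total",
        len(plots), sum(p.stem_map.n_trees for p in plots),
    )
    return plots
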