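"""Quadrat topography and the 34-variable plot environment table.

Topographic variables follow the forest-plot convention: each quadrat's
mean elevation is the mean of its four corner elevations; slope is the mean
of the angular slopes of the four planes fitted to each three-corner subset
of the corners; aspect comes from the downslope direction of the
least-squares plane and is sin-transformed to a sunward index in [-1, 1]
(+1 = equatorward-facing in either hemisphere); convexity is the focal
quadrat's mean elevation minus the mean of the mean elevations of its up to
eight adjoining quadrats.

The plot-level environment table has exactly 34 columns: 22 climatic
variables (19 bioclim, solar radiation, potential evapotranspiration,
aridity index) consumed as given tabular input, plus 12 topographic
variables (mean, range and coefficient of variation of elevation, slope,
transformed aspect and convexity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import CLIMATE_VARS

logger = logging.getLogger(__name__)

TOPO_BASE_VARS = ["elevation", "slope", "aspect", "convexity"]
TOPO_VARS = (
    [f"{v}_mean" for v in TOPO_BASE_VARS]
    + [f"{v}_range" for v in TOPO_BASE_VARS]
    + [f"{v}_cv" for v in TOPO_BASE_VARS]
)
#: Fixed column order of the assembled environment table.
ENV_COLUMNS = CLIMATE_VARS + TOPO_VARS

#: Sentinel written when a coefficient of variation is undefined (|mean|
#: below tolerance); logged wherever it is used.
CV_SENTINEL = 0.0
_CV_MEAN_TOL = 1e-9


@dataclass
class QuadratTopography:
    mean_elevation: float
    slope: float               # degrees, >= 0
    aspect_transformed: float  # sunward index in [-1, 1]
    convexity: float           # metres


def _three_corner_slopes(corners: np.ndarray, size: float) -> np.ndarray:
    """Angular slopes (degrees) of the four planes through 3 of 4 corners.

    ``corners`` ordered (z00, z10, z01, z11) for corner positions
    (0,0), (s,0), (0,s), (s,s). Each omitted corner leaves three points that
    define a plane with gradient read off the two edges of length ``size``.
    """
    z00, z10, z01, z11 = corners
    grads = [
        ((z10 - z00) / size, (z01 - z00) / size),  # omit z11
        ((z10 - z00) / size, (z11 - z10) / size),  # omit z01
        ((z11 - z01) / size, (z01 - z00) / size),  # omit z10
        ((z11 - z01) / size, (z11 - z10) / size),  # omit z00
    ]
    return np.degrees([np.arctan(np.hypot(b, c)) for b, c in grads])


def quadrat_topography(
    corners,
    size: float,
    neighbor_means=None,
    southern: bool = False,
) -> QuadratTopography:
    """Topographic variables of one quadrat from its four corner elevations.

    Parameters
    ----------
    corners : sequence of 4 floats
        Elevations (m) at (0,0), (s,0), (0,s), (s,s) of the quadrat.
    size : float
        Quadrat side length s in metres.
    neighbor_means : sequence of floats, optional
        Mean elevations of the adjoining quadrats (up to 8; edge quadrats
        pass fewer). Convexity is 0 when omitted or empty.
    southern : bool
        Southern-hemisphere flag; flips the aspect sign so +1 always means
        equatorward-facing.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4,) or not np.isfinite(corners).all():
        raise ValueError("need 4 finite corner elevations")
    mean_elev = float(corners.mean())
    slope = float(_three_corner_slopes(corners, size).mean())

    # least-squares plane over the 4 corners: gradient components
    z00, z10, z01, z11 = corners
    b = (z10 + z11 - z00 - z01) / (2 * size)
    c = (z01 + z11 - z00 - z10) / (2 * size)
    g = np.hypot(b, c)
    if g < 1e-12:
        aspect = 0.0  # flat: aspect undefined, transformed value 0
    else:
        # downslope unit vector is -(b, c)/g; its southward component is
        # c/g, the sin of the aspect angle measured from east
        aspect = float(c / g)
        if southern:
            aspect = -aspect
    if neighbor_means is not None and len(neighbor_means) > 0:
        convexity = mean_elev - float(np.mean(neighbor_means))
    else:
        convexity = 0.0
    return QuadratTopography(mean_elev, slope, aspect, convexity)


def topography_grid(
    corner_grid: np.ndarray, size: float, southern: bool = False
) -> pd.DataFrame:
    """Per-quadrat topography for a whole plot from its corner grid.

    ``corner_grid`` has shape (ny+1, nx+1); rows index y. Convexity uses
    however many of the 8 adjoining quadrats exist (edge handling).
    Returns a DataFrame with one row per quadrat in row-major (y, x) order
    and columns elevation, slope, aspect, convexity.
    """
    corner_grid = np.asarray(corner_grid, dtype=float)
    if not np.isfinite(corner_grid).all():
        raise ValueError("corner grid contains non-finite elevations")
    ny, nx = corner_grid.shape[0] - 1, corner_grid.shape[1] - 1
    mean_elev = (
        corner_grid[:-1, :-1] + corner_grid[:-1, 1:]
        + corner_grid[1:, :-1] + corner_grid[1:, 1:]
    ) / 4.0

    rows = []
    for j in range(ny):
        for i in range(nx):
            corners = (
                corner_grid[j, i], corner_grid[j, i + 1],
                corner_grid[j + 1, i], corner_grid[j + 1, i + 1],
            )
            nbrs = [
                mean_elev[jj, ii]
                for jj in range(max(j - 1, 0), min(j + 2, ny))
                for ii in range(max(i - 1, 0), min(i + 2, nx))
                if (jj, ii) != (j, i)
            ]
            t = quadrat_topography(corners, size, nbrs, southern)
            rows.append(
                {
                    "quadrat_id": f"q{j:03d}_{i:03d}",
                    "elevation": t.mean_elevation,
                    "slope": t.slope,
                    "aspect": t.aspect_transformed,
                    "convexity": t.convexity,
                }
            )
    return pd.DataFrame(rows).set_index("quadrat_id")


def plot_topo_summary(topo: pd.DataFrame) -> pd.Series:
    """Mean, range and CV of the four topographic variables over quadrats.

    CV = sd/mean (population sd); when |mean| is below tolerance the CV is
    undefined and set to :data:`CV_SENTINEL` with a log message.
    """
    if len(topo) < 2:
        raise ValueError("need >= 2 quadrats for plot-level topographic summaries")
    out = {}
    for v in TOPO_BASE_VARS:
        x = topo[v].to_numpy(dtype=float)
        mean = x.mean()
        out[f"{v}_mean"] = mean
        out[f"{v}_range"] = x.max() - x.min()
        sd = x.std()
        if abs(mean) < _CV_MEAN_TOL:
            if sd > _CV_MEAN_TOL:
                logger.info("CV of %s undefined (mean ~ 0); sentinel %s used", v, CV_SENTINEL)
            out[f"{v}_cv"] = CV_SENTINEL
        else:
            out[f"{v}_cv"] = sd / mean
    return pd.Series(out)[TOPO_VARS]


def assemble_environment(
    climate_table: pd.DataFrame, topo_summaries: pd.DataFrame
) -> pd.DataFrame:
    """Join climate (22 columns) and topography (12 columns) per plot.

    Column order is fixed to :data:`ENV_COLUMNS`. Missing plots or columns
    raise an assembly error naming the offender.
    """
    for name, tab, cols in (
        ("climate", climate_table, CLIMATE_VARS),
        ("topography", topo_summaries, TOPO_VARS),
    ):
        missing_cols = [c for c in cols if c not in tab.columns]
        if missing_cols:
            raise ValueError(f"{name} table missing columns: {missing_cols}")
    only_clim = set(climate_table.index) - set(topo_summaries.index)
    only_topo = set(topo_summaries.index) - set(climate_table.index)
    if only_clim or only_topo:
        raise ValueError(
            f"plot keys differ: climate-only {sorted(only_clim)}, "
            f"topography-only {sorted(only_topo)}"
        )
    env = pd.concat(
        [climate_table[CLIMATE_VARS], topo_summaries.loc[climate_table.index, TOPO_VARS]],
        axis=1,
    )
    bad = env.columns[env.isna().any()].tolist()
    if bad:
        badplots = env.index[env[bad].isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in columns {bad} for plots {badplots}")
    return env
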