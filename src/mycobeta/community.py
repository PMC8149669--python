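"""Stem maps, mycorrhizal assignment, and quadrat community matrices.

A stem map is the censused tree table of one forest-dynamics plot: every
free-standing woody stem above a DBH threshold with its map coordinates and
species. This module turns a stem map into quadrat x species abundance
matrices at a chosen quadrat scale and stratifies them by mycorrhizal type
(AM = arbuscular mycorrhizal, EcM = ectomycorrhizal, "other" = everything
else, including non-mycorrhizal and dual-status taxa under the default
policy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MYCORRHIZAL_TYPES = ("AM", "EcM", "other")
GROUPS = ("all", "AM", "EcM", "all_minus_AM", "all_minus_EcM")

STEM_COLUMNS = ["tree_id", "x_m", "y_m", "species", "dbh_cm"]


class LookupError_(KeyError):
    """A species is missing from the taxonomy lookup."""


@dataclass
class StemMap:
    """Mapped trees of one plot.

    Parameters
    ----------
    trees : pandas.DataFrame
        Columns ``tree_id, x_m, y_m, species, dbh_cm``; coordinates in
        metres from the plot origin, DBH in centimetres.
    plot_width, plot_height : float
        Plot rectangle dimensions in metres. Every tree must satisfy
        ``0 <= x < width`` and ``0 <= y < height``.
    """

    trees: pd.DataFrame
    plot_width: float
    plot_height: float

    def __post_init__(self) -> None:
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot dimensions must be positive")
        t = self.trees
        missing = [c for c in STEM_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"stem map missing columns: {missing}")
        if len(t):
            if (t.x_m < 0).any() or (t.x_m >= self.plot_width).any():
                raise ValueError("tree x coordinate outside plot rectangle")
            if (t.y_m < 0).any() or (t.y_m >= self.plot_height).any():
                raise ValueError("tree y coordinate outside plot rectangle")
            if (t.dbh_cm <= 0).any():
                raise ValueError("DBH must be positive")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def area_ha(self) -> float:
        return self.plot_width * self.plot_height / 1e4


@dataclass
class PlotMetadata:
    """Location and geometry of one plot (latitude signed, degrees)."""

    name: str
    latitude: float
    longitude: float
    elevation: float
    area_ha: float

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValueError(f"|latitude| > 90 for plot {self.name}")
        if not np.isfinite(self.elevation):
            raise ValueError(f"non-finite elevation for plot {self.name}")


@dataclass
class MycorrhizaTable:
    """Genus- and family-level mycorrhizal lookup plus a species taxonomy.

    Assignment follows the field convention: genus-level entry first, family
    level as fallback. Taxa recorded in the literature with two or more
    mycorrhizal types carry a dual-status flag and are resolved per policy
    (default: classified as "other").

    Attributes
    ----------
    genus_map, family_map : dict
        taxon name -> type in {"AM", "EcM", "other"}.
    taxonomy : dict
        species -> (genus, family).
    dual_status : set
        Genus or family names flagged as dual-status.
    non_tree : set
        Species of excluded growth forms (lianas, palms, shrubs).
    """

    genus_map: dict[str, str]
    family_map: dict[str, str]
    taxonomy: dict[str, tuple[str, str]]
    dual_status: set[str] = field(default_factory=set)
    non_tree: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for m in (self.genus_map, self.family_map):
            bad = {v for v in m.values()} - set(MYCORRHIZAL_TYPES)
            if bad:
                raise ValueError(f"unknown mycorrhizal types: {sorted(bad)}")


def assign_mycorrhizal_type(
    species: str, table: MycorrhizaTable, dual_policy: str = "other"
) -> str:
    """Resolve the mycorrhizal type of one species.

    Genus-level assignment takes precedence over family-level; species with
    neither are classified "other" with a logged warning. Dual-status taxa
    resolve per ``dual_policy``: "other" (default), "as_AM", or "as_EcM".

    Raises
    ------
    LookupError_
        If the species is absent from the taxonomy.
    """
    if dual_policy not in ("other", "as_AM", "as_EcM"):
        raise ValueError(f"unknown dual_policy {dual_policy!r}")
    try:
        genus, family = table.taxonomy[species]
    except KeyError:
        raise LookupError_(f"species {species!r} absent from taxonomy") from None

    for taxon, mapping in ((genus, table.genus_map), (family, table.family_map)):
        if taxon in mapping:
            if taxon in table.dual_status:
                return {"other": "other", "as_AM": "AM", "as_EcM": "EcM"}[dual_policy]
            return mapping[taxon]
    logger.warning("species %s unmapped at genus and family level; typed 'other'", species)
    return "other"


def filter_trees(stem_map: StemMap, min_dbh: float = 1.0) -> StemMap:
    """Retain trees with DBH >= ``min_dbh`` cm (inclusive), order preserved.

    The census standard is DBH >= 1 cm; some plots were censused from a
    larger threshold (e.g. 6 cm), handled by raising ``min_dbh``.
    """
    if min_dbh <= 0:
        raise ValueError("min_dbh must be positive")
    kept = stem_map.trees[stem_map.trees.dbh_cm >= min_dbh].reset_index(drop=True)
    if len(kept) == 0:
        logger.warning("DBH filter at %.3g cm removed every tree", min_dbh)
    return StemMap(kept, stem_map.plot_width, stem_map.plot_height)


def remove_non_trees(stem_map: StemMap, table: MycorrhizaTable) -> StemMap:
    """Drop species flagged as non-tree growth forms before gridding."""
    if not table.non_tree:
        return stem_map
    kept = stem_map.trees[~stem_map.trees.species.isin(table.non_tree)]
    return StemMap(kept.reset_index(drop=True), stem_map.plot_width, stem_map.plot_height)


@dataclass
class CommunityMatrix:
    """Quadrat x species abundance counts at one quadrat scale.

    ``counts`` is a DataFrame indexed by quadrat id with species columns;
    ``origins`` gives each quadrat's lower-left corner in metres;
    ``species_types`` maps each species column to its mycorrhizal type.
    """

    counts: pd.DataFrame
    origins: pd.DataFrame
    scale: float
    species_types: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("abundance counts must be non-negative")
        missing = set(self.counts.columns) - set(self.species_types.index)
        if missing:
            raise ValueError(f"species without mycorrhizal type: {sorted(missing)}")

    @property
    def n_quadrats(self) -> int:
        return len(self.counts)

    def nonempty_mask(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1) > 0


def grid_quadrats(
    stem_map: StemMap,
    scale: float,
    species_types: pd.Series | None = None,
    table: MycorrhizaTable | None = None,
    dual_policy: str = "other",
) -> CommunityMatrix:
    """Bin trees into square quadrats tiling the plot from the origin.

    Quadrats are half-open squares ``[k*scale, (k+1)*scale)``; a tree exactly
    on an internal boundary belongs to the quadrat it opens. Partial quadrats
    at the far edges are dropped and their trees excluded (logged), so every
    retained quadrat has equal area.

    Per-species mycorrhizal types come either from ``species_types`` (a
    Series) or are resolved from a :class:`MycorrhizaTable`.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if scale > stem_map.plot_width or scale > stem_map.plot_height:
        raise ValueError(
            f"quadrat scale {scale} m exceeds plot dimensions "
            f"{stem_map.plot_width} x {stem_map.plot_height} m"
        )
    nx = int(stem_map.plot_width // scale)
    ny = int(stem_map.plot_height // scale)

    t = stem_map.trees
    ix = np.floor(t.x_m.to_numpy() / scale).astype(int)
    iy = np.floor(t.y_m.to_numpy() / scale).astype(int)
    inside = (ix < nx) & (iy < ny)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info(
            "dropped %d trees in partial edge quadrats (scale %g m)", n_dropped, scale
        )

    quadrat_ids = [f"q{j:03d}_{i:03d}" for j in range(ny) for i in range(nx)]
    origins = pd.DataFrame(
        {
            "x0_m": [i * scale for j in range(ny) for i in range(nx)],
            "y0_m": [j * scale for j in range(ny) for i in range(nx)],
        },
        index=quadrat_ids,
    )

    species = sorted(t.species.unique())
    sp_idx = {s: k for k, s in enumerate(species)}
    counts = np.zeros((nx * ny, len(species)), dtype=np.int64)
    flat = iy[inside] * nx + ix[inside]
    cols = t.species.to_numpy()[inside]
    np.add.at(counts, (flat, [sp_idx[s] for s in cols]), 1)
    counts_df = pd.DataFrame(counts, index=quadrat_ids, columns=species)

    if species_types is None:
        if table is None:
            raise ValueError("provide species_types or a MycorrhizaTable")
        species_types = pd.Series(
            {s: assign_mycorrhizal_type(s, table, dual_policy) for s in species}
        )
    species_types = species_types.reindex(species)
    if species_types.isna().any():
        missing = species_types.index[species_types.isna()].tolist()
        raise ValueError(f"species without mycorrhizal type: {missing}")
    return CommunityMatrix(counts_df, origins, scale, species_types)


def stratify(matrix: CommunityMatrix, group: str) -> CommunityMatrix:
    """Restrict species columns to one mycorrhizal group.

    Groups: ``all`` (identity), ``AM``, ``EcM``, ``all_minus_AM``,
    ``all_minus_EcM``. Quadrats are retained even if they become empty;
    emptiness is handled by the pair-sampling stage. A group with zero
    species yields an empty matrix and a warning (the plot is later skipped
    for that group).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "all":
        return matrix
    types = matrix.species_types
    if group in ("AM", "EcM"):
        keep = types.index[types == group]
    else:
        excluded = group.removeprefix("all_minus_")
        keep = types.index[types != excluded]
    if len(keep) == 0:
        logger.warning("group %s has zero species in this matrix", group)
    return CommunityMatrix(
        matrix.counts[list(keep)], matrix.origins, matrix.scale, types.loc[list(keep)]
    )
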