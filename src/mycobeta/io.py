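"""Plain-text readers and writers for the pipeline's tabular formats.

Stem maps are TSV (tree_id, x_m, y_m, species, dbh_cm); plot metadata and
climate are key-value CSV; corner elevations are a dense CSV grid; taxonomy
and mycorrhiza lookups are CSV. Community matrices are wide CSV with one
row per quadrat.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community import (
    CommunityMatrix,
    MycorrhizaTable,
    PlotMetadata,
    StemMap,
    STEM_COLUMNS,
)


def write_stem_map(stem_map: StemMap, path) -> None:
    stem_map.trees[STEM_COLUMNS].to_csv(path, sep="\t", index=False)


def read_stem_map(path, plot_width: float, plot_height: float) -> StemMap:
    trees = pd.read_csv(path, sep="\t")
    return StemMap(trees, plot_width, plot_height)


def write_metadata(meta: PlotMetadata, path) -> None:
    pd.Series(
        {
            "name": meta.name,
            "latitude": meta.latitude,
            "longitude": meta.longitude,
            "elevation": meta.elevation,
            "area_ha": meta.area_ha,
        }
    ).to_csv(path, header=False)


def read_metadata(path) -> PlotMetadata:
    s = pd.read_csv(path, header=None, index_col=0)[1]
    return PlotMetadata(
        name=str(s["name"]),
        latitude=float(s["latitude"]),
        longitude=float(s["longitude"]),
        elevation=float(s["elevation"]),
        area_ha=float(s["area_ha"]),
    )


def write_climate(climate: pd.Series, path) -> None:
    climate.to_csv(path, header=False)


def read_climate(path) -> pd.Series:
    return pd.read_csv(path, header=None, index_col=0)[1].astype(float)


def write_corner_grid(grid: np.ndarray, path) -> None:
    np.savetxt(path, grid, delimiter=",")


def read_corner_grid(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def write_community_matrix(matrix: CommunityMatrix, path) -> None:
    wide = matrix.origins.join(matrix.counts)
    wide.index.name = "quadrat_id"
    wide.to_csv(path)


def read_community_matrix(path, scale: float, species_types: pd.Series) -> CommunityMatrix:
    wide = pd.read_csv(path, index_col="quadrat_id")
    wide.index.name = None
    origins = wide[["x0_m", "y0_m"]]
    counts = wide.drop(columns=["x0_m", "y0_m"]).astype(np.int64)
    return CommunityMatrix(counts, origins, scale, species_types.reindex(counts.columns))


def read_mycorrhiza_table(taxonomy_path, mycorrhiza_path) -> MycorrhizaTable:
    """Load the lookup pair: taxonomy CSV and mycorrhiza CSV.

    Taxonomy columns: species, genus, family, growth_form (non-"tree" rows
    are flagged for removal). Mycorrhiza columns: taxon, rank (genus or
    family), type (AM/EcM/other), dual_flag (0/1).
    """
    tax = pd.read_csv(taxonomy_path)
    myc = pd.read_csv(mycorrhiza_path)
    taxonomy = {
        r.species: (r.genus, r.family) for r in tax.itertuples(index=False)
    }
    non_tree = set(tax.species[tax.growth_form.str.lower() != "tree"])
    genus_map = {
        r.taxon: r.type for r in myc.itertuples(index=False) if r.rank == "genus"
    }
    family_map = {
        r.taxon: r.type for r in myc.itertuples(index=False) if r.rank == "family"
    }
    dual = set(myc.taxon[myc.dual_flag.astype(bool)])
    return MycorrhizaTable(genus_map, family_map, taxonomy, dual, non_tree)


def write_synthetic_plot(plot, out_dir) -> None:
    """Write one synthetic plot's stem map, metadata, climate and corners."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = plot.metadata.name
    write_stem_map(plot.stem_map, out / f"{name}_stems.tsv")
    write_metadata(plot.metadata, out / f"{name}_meta.csv")
    write_climate(plot.climate, out / f"{name}_climate.csv")
    write_corner_grid(plot.corner_elevations, out / f"{name}_corners.csv")
    plot.species_types.rename("mycorrhizal_type").to_csv(out / f"{name}_species_types.csv")
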