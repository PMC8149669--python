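import numpy as np
import pandas as pd
import pytest

from mycobeta.community import MycorrhizaTable, StemMap


@pytest.fixture
def small_stem_map() -> StemMap:
    """Nine trees of three species on a 100 x 100 m plot."""
    trees = pd.DataFrame(
        {
            "tree_id": [f"t{i}" for i in range(9)],
            "x_m": [5.0, 15.0, 20.0, 35.0, 55.0, 75.0, 85.0, 95.0, 99.9],
            "y_m": [5.0, 25.0, 45.0, 65.0, 5.0, 25.0, 85.0, 95.0, 99.9],
            "species": ["Alnus glutinosa", "Acer rubrum", "Quercus alba",
                        "Acer rubrum", "Quercus alba", "Alnus glutinosa",
                        "Acer rubrum", "Quercus alba", "Acer rubrum"],
            "dbh_cm": [0.5, 1.0, 6.0, 2.5, 12.0, 3.3, 40.0, 1.0, 7.7],
        }
    )
    return StemMap(trees, 100.0, 100.0)


@pytest.fixture
def lookup_table() -> MycorrhizaTable:
    return MycorrhizaTable(
        genus_map={"Acer": "AM", "Alnus": "EcM", "Dualis": "AM"},
        family_map={"Fagaceae": "EcM", "Sapindaceae": "AM"},
        taxonomy={
            "Acer rubrum": ("Acer", "Sapindaceae"),
            "Alnus glutinosa": ("Alnus", "Betulaceae"),
            "Quercus alba": ("Quercus", "Fagaceae"),
            "Mystery sp": ("Mysteria", "Mysteriaceae"),
            "Dualis arborea": ("Dualis", "Dualaceae"),
            "Liana liana": ("Liana", "Lianaceae"),
        },
        dual_status={"Dualis"},
        non_tree={"Liana liana"},
    )


def random_counts(rng: np.random.Generator, n_quadrats: int, n_species: int) -> np.ndarray:
    """Sparse random community counts with a lognormal-ish SAD."""
    lam = rng.lognormal(0.5, 1.0, n_species)
    return rng.poisson(lam, size=(n_quadrats, n_species))
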