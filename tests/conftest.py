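import numpy as np
import pandas as pd
import pytest

import traitgrad as tg
from traitgrad.datasets import zone_correlation_matrices


@pytest.fixture(scope="session")
def zone_matrices():
    """The three bundled per-zone 5x5 trait correlation matrices."""
    return zone_correlation_matrices()


@pytest.fixture()
def small_trait_table():
    """Two patches x one zone x two trees, two traits, two replicates."""
    rows = []
    for patch, size in (("P1", "small"), ("P3", "large")):
        for tree in ("t1", "t2"):
            for trait, base in (("LMA", 100.0), ("SD", 120.0)):
                for j, rep in enumerate(("r1", "r2")):
                    rows.append((patch, size, "core", tree, trait, rep,
                                 base + 10 * j + (5 if tree == "t2" else 0)))
    df = pd.DataFrame(rows, columns=["patch_id", "patch_size_class", "zone",
                                     "tree_id", "trait_name", "replicate_id", "value"])
    return tg.TraitTable(df)


def leeward_zone_config(n_trees, within_tree_cv=0.0, zone="leeward"):
    """Zone generator parameterised like the dry leeward edge."""
    matrices = zone_correlation_matrices()
    means = {"SD": 170.5, "TD": 10.7, "LMA": 273.0, "VD": 309.5, "VDi": 16.9}
    cvs = {"SD": 0.21, "TD": 0.29, "LMA": 0.27, "VD": 0.12, "VDi": 0.07}
    return tg.ZoneConfig(zone=zone, n_trees=n_trees, trait_means=means,
                         trait_cvs=cvs, correlation=matrices["leeward"],
                         within_tree_cv=within_tree_cv)


def single_zone_simulation(n_trees, seed, within_tree_cv=0.0):
    zc = leeward_zone_config(n_trees, within_tree_cv)
    return tg.SimulationConfig(
        [tg.PatchConfig("P", "large", {"leeward": zc})], seed=seed
    )
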