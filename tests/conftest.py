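import dendropy
import numpy as np
import pandas as pd
import pytest

from elevdiv.belts import BeltMatrix, build_grid


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def four_tip_tree() -> dendropy.Tree:
    """Balanced 4-tip tree with unit branch lengths; the worked example for
    PD/MPD/NRI hand calculations."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def matrix_from_sets(belt_taxa: list[set[str]], belt_width: float = 100.0) -> BeltMatrix:
    """Build a BeltMatrix directly from per-belt taxon sets (ascending)."""
    n = len(belt_taxa)
    grid = build_grid("test", 0.0, n * belt_width, belt_width)
    taxa = sorted(set().union(*belt_taxa))
    pres = np.zeros((n, len(taxa)), dtype=np.int8)
    for i, s in enumerate(belt_taxa):
        for t in s:
            pres[i, taxa.index(t)] = 1
    df = pd.DataFrame(pres, index=grid.lower_bounds, columns=taxa)
    df.index.name = "belt_lo"
    return BeltMatrix(grid, df)


@pytest.fixture
def matrix_builder():
    return matrix_from_sets
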