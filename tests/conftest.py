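import numpy as np
import pandas as pd
import pytest

from paracong.io import CommunityTable, PhyloTree, TaxonomyMap


@pytest.fixture
def rng():
    return np.random.default_rng(20240725)


@pytest.fixture
def cherry_tree():
    return PhyloTree.from_newick("((A:1,B:1):0.5,C:2);")


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        {"s1": [5, 3, 2], "s2": [1, 4, 5], "s3": [0, 2, 8], "s4": [6, 6, 0]},
        index=["A", "B", "C"],
    )
    return CommunityTable(data)


@pytest.fixture
def small_taxonomy():
    return TaxonomyMap(
        {
            "A": {"kingdom": "Fungi", "phylum": "Ascomycota"},
            "B": {"kingdom": "Fungi", "phylum": "Ascomycota"},
            "C": {"kingdom": "Fungi", "phylum": "Basidiomycota"},
        }
    )


def random_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """Random binary tree as a Newick string, independent of the package's
    own Yule generator (used to feed oracle comparisons)."""
    parts = [f"L{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    newick = parts[0]
    newick = newick.rsplit(":", 1)[0] + ";"
    return PhyloTree.from_newick(newick)


def random_table(taxa, n_samples: int, rng: np.random.Generator) -> CommunityTable:
    counts = rng.integers(0, 50, size=(len(taxa), n_samples))
    # guarantee positive sample totals
    counts[rng.integers(len(taxa)), :] += 1
    cols = [f"s{j}" for j in range(n_samples)]
    return CommunityTable(pd.DataFrame(counts, index=list(taxa), columns=cols))
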