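import io

import numpy as np
import pandas as pd
import pytest

import hypertraps as ht


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix() -> ht.TraitMatrix:
    """Four taxa, three modes, with wild (1) and human-influenced (2) entries."""
    values = pd.DataFrame(
        [[1, 0, 2], [1, 1, 0], [0, 0, 0], [2, 1, 1]],
        index=pd.Index(["wren", "vole", "slug", "ape"], name="taxon"),
        columns=["poke", "drop", "carry"],
    )
    annotations = pd.DataFrame(
        {"aquatic": [False, False, True, False],
         "primate": [False, False, False, True],
         "bird": [True, False, False, False],
         "rank": ["family", "genus", "class", "genus"]},
        index=values.index,
    )
    return ht.TraitMatrix(values=values, annotations=annotations)


@pytest.fixture
def tiny_taxonomy() -> ht.Taxonomy:
    return ht.Taxonomy.from_newick_string("((wren,vole)inner,(slug,ape)other)root;")


@pytest.fixture(scope="session")
def packaged_matrix() -> ht.TraitMatrix:
    return ht.load_packaged_matrix()


@pytest.fixture(scope="session")
def packaged_taxonomy() -> ht.Taxonomy:
    return ht.load_packaged_taxonomy()


def matrix_from_csv_text(text: str) -> ht.TraitMatrix:
    return ht.read_trait_matrix(io.StringIO(text))
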