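import numpy as np
import pytest

import funcsens as fs


@pytest.fixture(scope="session")
def schema():
    return fs.default_fish_schema()


@pytest.fixture(scope="session")
def toy_matrix():
    """3-species worked example: d(A,B)=0.2, d(A,C)=d(B,C)=0.6."""
    return fs.DissimilarityMatrix(
        np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]), ["A", "B", "C"]
    )


@pytest.fixture(scope="session")
def toy_tree(toy_matrix):
    return fs.build_upgma_dendrogram(toy_matrix)


@pytest.fixture
def toy_assemblage():
    return fs.Assemblage(
        site_id="toy", system="river", abundances={"A": 0.01, "B": 0.5, "C": 0.2}
    )


def random_trait_table(n_species, schema, rng):
    """Uniform random trait table over the schema's categories."""
    import pandas as pd

    data = {
        t.name: rng.choice(list(t.categories), size=n_species) for t in schema.traits
    }
    names = [f"s{i:03d}" for i in range(n_species)]
    return fs.TraitTable(pd.DataFrame(data, index=names), schema)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pool_only_config(pool_size, **kw):
    """GeneratorConfig used only to draw a species pool (no assemblages)."""
    return fs.GeneratorConfig(
        pool_size=pool_size,
        n_sites={"estuary": 0, "lake": 0, "river": 0},
        **kw,
    )
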