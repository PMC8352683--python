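import numpy as np
import pytest

from symdx.taxonomy import Category, Disease, DiseaseTaxonomy, Subclass


def build_taxonomy(code_base: int, shape: list[list[int]],
                   n_symptoms: int = 8) -> DiseaseTaxonomy:
    """Small taxonomy builder: shape[b-1][j-1] = number of diseases."""
    categories = tuple(
        Category(
            b=b, name=f"cat{b}",
            subclasses=tuple(
                Subclass(
                    j=j, name=f"sub{b}{j}",
                    diseases=tuple(Disease(t=t, name=f"dis{b}{j}{t}")
                                   for t in range(1, n_dis + 1)),
                )
                for j, n_dis in enumerate(shape[b - 1], start=1)
            ),
        )
        for b in range(1, len(shape) + 1)
    )
    names = ("gender",) + tuple(f"s{i}" for i in range(1, n_symptoms))
    return DiseaseTaxonomy(code_base=code_base, symptom_names=names,
                           categories=categories)


@pytest.fixture(scope="session")
def worked_example():
    from symdx.synthetic import worked_example_fixture

    return worked_example_fixture()


@pytest.fixture(scope="session")
def cube_taxonomy():
    """3 categories x 3 subclasses x 3 diseases, code base 30."""
    return build_taxonomy(30, [[3, 3, 3]] * 3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
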