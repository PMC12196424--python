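import numpy as np
import pytest

from regionenrich.atlas_io import ExpressionAtlas
from regionenrich.high_expression import high_expression_sets
from regionenrich.synthetic_data import Program, SyntheticSpec, generate_atlas


@pytest.fixture
def tiny_atlas() -> ExpressionAtlas:
    """3 genes x 4 regions, hand-checkable values."""
    return ExpressionAtlas(
        genes=("g1", "g2", "g3"),
        regions=("A", "B", "C", "D"),
        values=np.array(
            [
                [10.0, 0.0, 0.0, 0.0],
                [5.0, 5.0, 5.0, 5.0],
                [1.0, 2.0, 3.0, 4.0],
            ]
        ),
    )


@pytest.fixture(scope="session")
def planted_atlas():
    """200 genes x 20 regions with one strong 15-gene program on region 5."""
    spec = SyntheticSpec(
        n_genes=200,
        n_regions=20,
        programs=(Program(region_ids=(5,), n_genes=15, effect_multiplier=40.0),),
        seed=11,
    )
    return generate_atlas(spec)


@pytest.fixture(scope="session")
def planted_index(planted_atlas):
    atlas, _ = planted_atlas
    return high_expression_sets(atlas)
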