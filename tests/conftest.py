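import numpy as np
import pytest
from hypothesis import settings

from littersuccession.io import FeatureTable, parse_tree

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def four_leaf_tree():
    return parse_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5, 0, 2],
            [3, 4, 0],
            [0, 1, 7],
            [2, 2, 2],
        ]
    )
    return FeatureTable(("A", "B", "C", "D"), ("s1", "s2", "s3"), counts)
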