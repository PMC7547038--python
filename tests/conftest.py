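import numpy as np
import pytest

from hemagl import default_grammar, generate_items, remap_letters
from hemagl.materials import default_transfer_mapping


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


@pytest.fixture(scope="session")
def item_sets(grammar):
    """Default synthetic materials: standard item set + transfer twin."""
    rng = np.random.default_rng(2024)
    standard = generate_items(grammar, rng=rng)
    transfer = remap_letters(standard, default_transfer_mapping())
    return {"standard": standard, "transfer": transfer}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
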