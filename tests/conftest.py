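import numpy as np
import pandas as pd
import pytest

from epivuln.registry import IndicatorDefinition, IndicatorRegistry, load_packaged_registry


@pytest.fixture(scope="session")
def packaged_registry() -> IndicatorRegistry:
    return load_packaged_registry()


@pytest.fixture(scope="session")
def toy_registry() -> IndicatorRegistry:
    """Three indicators covering both orientations, two natures and both
    relation tags."""
    return IndicatorRegistry(
        [
            IndicatorDefinition("A", "attr A", "stimulant", "D", frozenset({"intended"})),
            IndicatorDefinition("B", "attr B", "destimulant", "D", frozenset({"unintended"})),
            IndicatorDefinition("C", "attr C", "destimulant", "S", frozenset({"intended"})),
        ]
    )


@pytest.fixture(scope="session")
def toy_table() -> pd.DataFrame:
    """Four districts, hand-checkable values for the toy registry."""
    return pd.DataFrame(
        {"A": [2.0, 4.0, 6.0, 8.0], "B": [10.0, 0.0, 5.0, 10.0], "C": [1.0, 3.0, 3.0, 5.0]},
        index=pd.Index(["d1", "d2", "d3", "d4"], name="district_id"),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200430)
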