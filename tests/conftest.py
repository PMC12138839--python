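import numpy as np
import pytest

from dtwnet import Attribute, AttributeSchema, PanelDataset


@pytest.fixture
def tiny_schema():
    """Three attributes, one with inverted valence."""
    return AttributeSchema.from_attributes(
        [
            Attribute("depression", "Depression"),
            Attribute("anxiety", "Anxiety"),
            Attribute("well_being", "Well-being", higher_is_worse=False),
        ]
    )


@pytest.fixture
def make_panel():
    """Factory for small panels from a (S, T, K) array."""

    def _make(values, attributes=None, imputation_index=None):
        values = np.asarray(values, dtype=float)
        s, t, k = values.shape
        subjects = tuple(f"S{i:04d}" for i in range(1, s + 1))
        attributes = tuple(attributes or (f"a{j + 1}" for j in range(k)))
        return PanelDataset(subjects, tuple(range(t)), attributes, values, imputation_index)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
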