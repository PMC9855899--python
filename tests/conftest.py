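import numpy as np
import pytest

from afmtexture import ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def make_image():
    """Factory: random (or given) raster wrapped as a height ChannelImage."""

    def _make(values=None, n=16, seed=0, pitch=19.53, units="nm", kind="height"):
        if values is None:
            values = np.random.default_rng(seed).standard_normal((n, n))
        return ChannelImage(np.asarray(values, dtype=float), pitch, units, kind)

    return _make


@pytest.fixture(scope="session")
def toy_table():
    """Small separable two-class feature table for classifier tests.

    Two informative features separated by 5 training sd plus one pure-noise
    feature; 30 cells per class.  The high class is the exact mirror image
    of the low class about the midpoint, so the set is symmetric by
    construction and the midpoint must score probability 1/2.
    """
    import pandas as pd

    from afmtexture import FeatureTable

    rng = np.random.default_rng(7)
    n = 30
    x_low = np.column_stack(
        [rng.normal(0, 1, n), rng.normal(0, 1, n), rng.normal(0, 1, n)]
    )
    x_high = 5.0 - x_low
    frame = pd.DataFrame(
        np.vstack([x_low, x_high]),
        index=[f"low_{i}" for i in range(n)] + [f"high_{i}" for i in range(n)],
        columns=pd.MultiIndex.from_tuples(
            [("height", "Sa"), ("height", "Sq"), ("height", "Sku")]
        ),
    )
    labels = pd.Series(["low"] * n + ["high"] * n, index=frame.index, dtype=object)
    return FeatureTable(frame, labels)
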