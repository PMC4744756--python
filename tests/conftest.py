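import numpy as np
import pandas as pd
import pytest

from hairpinhb import GeometrySeries, HBCriteria

CLOSED_GEOM = (2.2, 160.0)
OPEN_GEOM = (6.0, 90.0)


def series_from_patterns(pattern_runs, closed=CLOSED_GEOM, open_=OPEN_GEOM):
    """Deterministic GeometrySeries whose classification reproduces the
    given per-run pattern sequences exactly (no noise)."""
    blocks = []
    for r, run in enumerate(pattern_runs):
        block = {"run": np.full(len(run), r), "frame": np.arange(len(run))}
        for b, label in enumerate(["HB1", "HB2", "HB3", "HB4"]):
            d = np.array([closed[0] if p[b] == "c" else open_[0] for p in run])
            a = np.array([closed[1] if p[b] == "c" else open_[1] for p in run])
            block[f"{label}_dist"] = d
            block[f"{label}_ang"] = a
        blocks.append(pd.DataFrame(block))
    return GeometrySeries(
        data=pd.concat(blocks, ignore_index=True), bond_labels=["HB1", "HB2", "HB3", "HB4"]
    )


@pytest.fixture
def criteria():
    return HBCriteria()


@pytest.fixture
def mixed_series():
    """Two runs with a hand-checkable pattern mix."""
    return series_from_patterns([["cccc", "cccc", "oooo"], ["oooo", "cocc"]])
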