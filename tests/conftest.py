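"""Shared fixtures: tiny hand-built atlases and a seeded random-atlas factory."""

import numpy as np
import pandas as pd
import pytest

from pollenscreen.atlas_io import ExpressionAtlas


@pytest.fixture
def tiny_atlas() -> ExpressionAtlas:
    """3 genes x 2 tissues with the values used in the I/O examples."""
    frame = pd.DataFrame(
        [[1.0, 2.0], [0.0, 5.0], [10.0, 0.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["pollen", "root"],
    )
    return ExpressionAtlas(frame)


@pytest.fixture
def random_atlas_factory():
    """Factory for seeded random atlases mixing zeros, trace and large values."""

    def make(seed: int, n_genes: int = 40, n_tissues: int = 5) -> ExpressionAtlas:
        rng = np.random.default_rng(seed)
        values = rng.lognormal(mean=1.0, sigma=2.0, size=(n_genes, n_tissues))
        values[rng.random(values.shape) < 0.15] = 0.0
        frame = pd.DataFrame(
            values,
            index=pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id"),
            columns=[f"t{j}" for j in range(n_tissues)],
        )
        return ExpressionAtlas(frame)

    return make
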