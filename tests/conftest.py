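from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirdiffreg.design import PoolDesign

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def design() -> PoolDesign:
    return PoolDesign()


def matrix_from_group_means(means: dict[str, dict[str, float]], design: PoolDesign) -> pd.DataFrame:
    """Zero-variance RPM matrix: every replicate pool equals its group mean.

    ``means`` maps element id -> {"HA_sham": value, ...}.
    """
    rows = {}
    for element, group_means in means.items():
        row = {}
        for (line, cond), pools in design.groups.items():
            value = group_means[f"{line}_{cond}"]
            for pool in pools:
                row[pool] = value
        rows[element] = row
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)[design.pools]


@pytest.fixture
def group_mean_matrix(design):
    def build(means: dict[str, dict[str, float]]) -> pd.DataFrame:
        return matrix_from_group_means(means, design)

    return build


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
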