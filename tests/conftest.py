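from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refstab import CtTable


def table_from_matrix(
    mat: dict[str, list[float]],
    groups: list[str] | None = None,
    template: str = "total",
) -> CtTable:
    """Build a collapsed CtTable from gene -> per-sample Ct lists."""
    n = len(next(iter(mat.values())))
    if groups is None:
        half = n // 2
        groups = ["egg"] * half + ["cortex"] * (n - half)
    samples = [f"s{i + 1}" for i in range(n)]
    rows = [
        {
            "gene": g,
            "sample": samples[i],
            "group": groups[i],
            "template": template,
            "replicate": 1,
            "ct": v[i],
        }
        for g, v in mat.items()
        for i in range(n)
    ]
    return CtTable.from_frame(pd.DataFrame(rows))


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int):
    """Random Ct matrix in the practical range, as plain python lists."""
    mat = {}
    for gi in range(n_genes):
        mu = rng.uniform(14, 32)
        sigma = rng.uniform(0.1, 1.5)
        mat[f"g{gi:02d}"] = list(mu + rng.normal(0, sigma, size=n_samples))
    return mat


@pytest.fixture
def small_table():
    return table_from_matrix(
        {
            "A": [20.0, 21.0, 22.0, 20.5],
            "B": [25.0, 26.0, 27.0, 25.5],
            "C": [30.0, 30.2, 31.0, 30.9],
        }
    )
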