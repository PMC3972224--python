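from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oralblocks import (
    MultiblockDataset,
    SyntheticConfig,
    VariableBlock,
    generate_dataset,
    prepare_dataset,
)


def random_multiblock(
    seed: int,
    n: int = 20,
    block_sizes: tuple[int, ...] = (4, 5, 3),
    p_y: int = 3,
) -> MultiblockDataset:
    """Unstructured Gaussian multiblock dataset (no latent signal)."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i:02d}" for i in range(n)], name="subject_id")
    y = VariableBlock(
        "Y",
        "response",
        pd.DataFrame(
            rng.standard_normal((n, p_y)), index=idx,
            columns=[f"y{j}" for j in range(p_y)],
        ),
    )
    xs = [
        VariableBlock(
            f"X{i + 1}",
            "predictor",
            pd.DataFrame(
                rng.standard_normal((n, p)), index=idx,
                columns=[f"x{i + 1}_{j}" for j in range(p)],
            ),
        )
        for i, p in enumerate(block_sizes)
    ]
    return MultiblockDataset(y=y, x_blocks=xs)


@pytest.fixture(scope="session")
def study_dataset() -> MultiblockDataset:
    """Default study-shaped synthetic dataset, feature pipeline applied."""
    replicate_ds, _ = generate_dataset(SyntheticConfig(seed=11))
    return prepare_dataset(replicate_ds)
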