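"""Shared fixtures: small synthetic cohorts prepared through the full
preprocessing chain (bin -> filter/split -> impute -> within-normalize)."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from triomics.synthetic import BlockSpec, CohortConfig, generate_cohort
from triomics.tensors import (
    DEFAULT_BIN_SPEC,
    bin_to_tensor,
    filter_and_split,
    within_normalize,
)
from triomics.tucker import impute_missing


def make_cohort(
    seed: int,
    effect: float,
    n_pairs: int = 20,
    n_features: int = 60,
    n_informative: int = 3,
    missing_rate: float = 0.1,
    controls_per_case: int = 1,
    block: str = "gene_expression",
    n_validation_pairs: int = 0,
):
    cfg = CohortConfig(
        n_pairs=n_pairs,
        block_specs=(BlockSpec(block, n_features, controls_per_case),),
        n_informative_per_block=n_informative,
        effect_size=effect,
        missing_rate=missing_rate,
        seed=seed,
        n_validation_pairs=n_validation_pairs,
    )
    return generate_cohort(cfg), cfg


def prepared_tensor(seed: int, effect: float, impute_ranks=(2, 2, 2), **kw):
    """Normalized, imputed analysis tensor with labels, pair ids and truth."""
    (meas, design, truth), _ = make_cohort(seed, effect, **kw)
    block = design["blocks"].iloc[0].split(";")[0]
    tensor = bin_to_tensor(meas, DEFAULT_BIN_SPEC, block)
    ana, _ = filter_and_split(tensor, design)
    filled, _ = impute_missing(ana, ranks=impute_ranks)
    complete = replace(filled, mask=np.ones_like(filled.mask))
    norm = within_normalize(complete, design)
    didx = design.set_index("subject_id")
    labels = np.array([didx.loc[s, "role"] for s in norm.subject_ids])
    pairs = np.array([didx.loc[s, "pair_id"] for s in norm.subject_ids])
    return norm, labels, pairs, truth


@pytest.fixture(scope="session")
def signal_tensor():
    """40-pair 1:1 cohort with a strong planted early signal."""
    return prepared_tensor(7, 2.0, n_pairs=40, n_features=100, n_informative=5)


@pytest.fixture(scope="session")
def null_tensor():
    """20-pair cohort with no case-control difference."""
    return prepared_tensor(11, 0.0)
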