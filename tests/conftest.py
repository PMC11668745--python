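"""Shared fixtures: the study-condition synthetic cohorts and posteriors.

The heavy artifacts (cross-validated classifier run, LSIRM recovery chain)
are session-scoped so property tests and end-to-end checks share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from fcnfusion.attention import AttnConfig, train_and_extract
from fcnfusion.datatypes import AttentionMatrix
from fcnfusion.fcn import pearson_matrix
from fcnfusion.lsirm import McmcConfig, run_mcmc
from fcnfusion.synthetic import (
    CohortSpec,
    ItemResponseSpec,
    simulate_cohort,
    simulate_item_response,
)

# ---- separable two-group cohort (classifier study conditions) -------------

SEPARABLE_SPEC = CohortSpec(
    n_rois=20,
    n_timepoints=150,
    n_subjects_per_group={"A": 15, "B": 15},
    block_partition=[list(range(8))],
    within_block_corr_by_group={"A": [0.6], "B": [0.1]},  # gap 0.5
    noise_ar1=0.3,
    seed=314,
)

ATTN_TEST_CFG = AttnConfig(
    n_heads=16, d_k=2, dropout=0.9, batch_size=8, learning_rate=0.01,
    max_epochs=60, cv_folds=10, seed=20,
)


@pytest.fixture(scope="session")
def separable_cohort():
    return simulate_cohort(SEPARABLE_SPEC)


@pytest.fixture(scope="session")
def separable_inputs(separable_cohort):
    return [pearson_matrix(ts) for ts in separable_cohort]


@pytest.fixture(scope="session")
def separable_cv(separable_cohort, separable_inputs):
    """(cv_accuracy, attention matrices) for the strongly separable cohort."""
    groups = [ts.group for ts in separable_cohort]
    return train_and_extract(
        separable_inputs, groups, ATTN_TEST_CFG,
        subject_ids=[ts.subject_id for ts in separable_cohort],
        roi_labels=separable_cohort[0].roi_labels,
    )


# ---- LSIRM recovery fixture ----------------------------------------------

RECOVERY_SPEC = ItemResponseSpec(
    n_subjects=60, n_rois=30, noise_sd=0.1,
    cluster_centers=[(-2.0, 0.0), (2.0, 0.0)], seed=42,
)

# jump scales sized to the fixture's latent-position scale (~2); the
# package defaults target much smaller-scale CV data
RECOVERY_MCMC = McmcConfig(
    n_iterations=20_000, burn_in=4_000, thin=4,
    jump_theta=0.1, jump_beta=0.1, jump_u=0.1, jump_v=0.1, seed=7,
)


@pytest.fixture(scope="session")
def recovery_data():
    return simulate_item_response(RECOVERY_SPEC)


@pytest.fixture(scope="session")
def recovery_posterior(recovery_data):
    y, _ = recovery_data
    return run_mcmc(y, RECOVERY_MCMC)


# ---- synthetic attention matrices ----------------------------------------

def random_attention_matrices(
    n_subjects: int, n_rois: int, seed: int, group: str = "A",
    roi_labels: list[str] | None = None,
) -> list[AttentionMatrix]:
    """Row-stochastic matrices from softmaxed Gaussian scores."""
    rng = np.random.default_rng(seed)
    if roi_labels is None:
        roi_labels = [f"ROI_{j + 1:03d}" for j in range(n_rois)]
    out = []
    for i in range(n_subjects):
        scores = rng.standard_normal((n_rois, n_rois))
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        out.append(
            AttentionMatrix(
                values=e / e.sum(axis=1, keepdims=True),
                subject_id=f"{group}{i:03d}",
                group=group,
                roi_labels=roi_labels,
            )
        )
    return out
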