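import numpy as np
import pytest

from fdtica import (
    GeneratorParams,
    GroundTruthICAMixture,
    SearchGrid,
    generate_study_cohort,
    run_pipeline,
)


@pytest.fixture(scope="session")
def gen_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def small_cohort():
    """150 normal + 100 abnormal synthetic fields, fixed seed."""
    return generate_study_cohort(150, 100, seed=711)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """A cheap end-to-end pipeline run shared by axis/pattern/severity tests."""
    grid = SearchGrid(cluster_counts=(2,), axis_maxima=(6,), mixture_components=(3,),
                      n_restarts=2, n_iterations=60, master_seed=5)
    return run_pipeline(small_cohort, grid)


def make_ica_truth(rng, K=1, D=12, L=2, m=2, mix_scale=3.0, noise_sd=0.3,
                   means=None, weights=None):
    """Well-conditioned mixture-of-ICA ground truth with bimodal sources.

    Mixing columns are orthogonal with distinct norms; equal norms with
    identical symmetric sources would leave the in-subspace rotation
    unidentifiable (the source distribution would be square-symmetric).
    """
    col_scale = mix_scale * (1.0 - 0.3 * np.arange(L) / max(L - 1, 1))
    mixing = np.stack([
        np.linalg.qr(rng.standard_normal((D, L)))[0] * col_scale[None, :]
        for _ in range(K)
    ])
    return GroundTruthICAMixture(
        weights=np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float),
        means=np.zeros((K, D)) if means is None else np.asarray(means, float),
        mixing=mixing,
        source_weights=np.full((K, L, m), 1.0 / m),
        source_means=np.tile(np.linspace(-1.0, 1.0, m), (K, L, 1)),
        source_sds=np.full((K, L, m), 0.3),
        noise_sd=np.full((K, D), noise_sd),
    )


def amari_distance(A_est: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation- and scale-invariant mixing-recovery discrepancy in [0, 1]."""
    P = np.abs(np.linalg.pinv(A_est) @ A_true)
    mdim = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * mdim * (mdim - 1)))
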