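import numpy as np
import pandas as pd
import pytest

from csss.io import ExpressionMatrix
from csss.synth import SyntheticSpec, Subpopulation, generate, orthonormal_processes


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix(rng):
    """Random lognormal 60-cell x 5-marker panel, two conditions."""
    values = np.exp(rng.normal(5.0, 0.5, size=(60, 5)))
    labels = np.array(["control"] * 30 + ["treated"] * 30, dtype=object)
    return ExpressionMatrix(values, ["Her2", "EGFR", "cMet", "MUC1", "ECadherin"],
                            [f"c{j}" for j in range(60)], labels)


def four_subpop_spec(n_cells=2500, seed=7, noise_sigma=0.05):
    """Small balanced scenario: 6 markers, 2 processes, 4 planted subpopulations.

    Each process carries equal positive and negative mass, and the baseline
    is uniform, so planted and fitted parameterizations coincide.
    """
    seeds = np.zeros((6, 2))
    seeds[[0, 1], 0] = [0.8, 0.6]
    seeds[[2, 3], 1] = [0.7, -0.7]
    baseline = np.full(6, 300.0)
    processes = orthonormal_processes(seeds, against=np.log(baseline))
    subs = [
        Subpopulation("p1_up", (1, 0), {"control": 0.20}),
        Subpopulation("p1_dn", (-1, 0), {"control": 0.20}),
        Subpopulation("p2_up", (0, 1), {"control": 0.15}),
        Subpopulation("p2_dn", (0, -1), {"control": 0.15}),
    ]
    return SyntheticSpec(
        marker_names=[f"m{j}" for j in range(6)],
        baseline=baseline,
        processes=processes,
        subpopulations=subs,
        conditions=["control"],
        n_cells=n_cells,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted():
    """Generated small planted scenario shared across tests (read-only)."""
    spec = four_subpop_spec()
    mat, truth = generate(spec)
    return spec, mat, truth


def match_processes(fitted_G: np.ndarray, planted: np.ndarray):
    """Map fitted constraint columns to planted ones by max |cosine|.

    Returns (match indices, signs, cosines) for fitted columns 1..K.
    """
    M = fitted_G[:, 1:].T @ planted
    match = np.abs(M).argmax(axis=1)
    signs = np.sign(M[np.arange(M.shape[0]), match])
    cosines = np.abs(M).max(axis=1)
    return match, signs, cosines
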