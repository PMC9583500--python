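"""Thin PCA / t-SNE baselines for comparison with CSSS partitioning.

Non-contractual utilities: conventional dimensionality reduction recovers
dominant variance axes but does not say which processes are active in each
cell, which is the whole point of the barcode route.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io import ExpressionMatrix

__all__ = ["pca_embedding", "tsne_embedding"]


def _log(mat: ExpressionMatrix, offset: float) -> np.ndarray:
    return np.log(mat.values + offset)


def pca_embedding(mat: ExpressionMatrix, n_components: int = 2, offset: float = 1.0) -> np.ndarray:
    """PCA of the log intensities (centered, unlike the surprisal route)."""
    return PCA(n_components=n_components).fit_transform(_log(mat, offset))


def tsne_embedding(mat: ExpressionMatrix, n_components: int = 2, offset: float = 1.0,
                   seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE of the log intensities; seeded, but inherently non-deterministic
    across library versions."""
    return TSNE(n_components=n_components, random_state=seed,
                perplexity=perplexity, init="pca").fit_transform(_log(mat, offset))
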