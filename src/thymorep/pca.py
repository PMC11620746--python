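"""PCA of log-transformed, z-scored count features."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "log_z_transform", "run_pca", "top_contributors"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_fraction: np.ndarray
    contributions: pd.DataFrame  # features x components, columns sum to 1

    @property
    def feature_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def log_z_transform(counts: pd.DataFrame, pseudocount: float = 0.01) -> pd.DataFrame:
    """log10 with a pseudocount for zeros, then per-feature z-scoring.

    The pseudocount replaces only unobserved (zero) counts.  Features
    that are constant across samples (zero SD) are dropped with a
    warning.
    """
    x = counts.astype(float).copy()
    if (x.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    x[x == 0] = pseudocount
    x = np.log10(x)
    sd = x.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index
    if len(constant):
        logger.warning("dropping %d zero-variance features", len(constant))
        x = x.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (x - x.mean(axis=0)) / sd


def run_pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA by SVD of the column-centred matrix.

    Sign convention: within each component the largest-magnitude
    loading is made positive.  Variance fractions are taken over all
    ``min(n_samples, n_features)`` components and sum to one.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: flip so the max-|loading| entry is positive
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    variance_fraction = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=comp_names)
    contributions = loadings**2
    contributions = contributions / contributions.sum(axis=0)
    return PCAResult(scores, loadings, variance_fraction, contributions)


def top_contributors(result: PCAResult, component: str | int, n: int = 10) -> pd.DataFrame:
    """Features ranked by squared-loading contribution to one component."""
    if isinstance(component, int):
        component = f"PC{component}"
    if component not in result.loadings.columns:
        raise ValueError(f"no component {component!r}")
    if n > len(result.loadings):
        warnings.warn("n exceeds feature count; truncating")
        n = len(result.loadings)
    df = pd.DataFrame(
        {
            "loading": result.loadings[component],
            "contribution": result.contributions[component],
        }
    )
    return df.sort_values("contribution", ascending=False).head(n)
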