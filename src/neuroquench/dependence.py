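"""Bivariate dependence measures used on simulated population activity."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["pearson", "spearman", "mutual_information", "fisher_z"]


def pearson(x, y) -> float:
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    return float(stats.spearmanr(x, y).statistic)


def fisher_z(r):
    """Fisher z-transform atanh(r), applied before averaging correlations."""
    return np.arctanh(r)


def mutual_information(x, y, bins: int = 20) -> float:
    """Plug-in mutual information (nats) from a fixed-bin 2D histogram.

    Each margin is binned into ``bins`` equal-width bins over its own observed
    range.  For identical inputs this reduces to the entropy of the binned
    marginal, MI(X, X) = H(X).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def binned_entropy(x, bins: int = 20) -> float:
    """Entropy (nats) of the equal-width histogram marginal; H(X) = MI(X, X)."""
    counts, _ = np.histogram(np.asarray(x, dtype=float), bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))
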