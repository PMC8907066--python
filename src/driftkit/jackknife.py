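"""Weighted block-jackknife variance estimation.

Implements the weighted delete-one jackknife of Busing, Meijer & van der
Leeden (1999).  With equal weights it reduces to the textbook formula
se^2 = ((B-1)/B) * sum_j (theta_{-j} - mean)^2.
"""
from __future__ import annotations

import numpy as np


def jackknife_se(estimate: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Standard error of a scalar estimate from delete-one-block estimates."""
    cov = jackknife_cov(np.atleast_1d(estimate), np.asarray(loo)[:, None], weights)
    return float(np.sqrt(cov[0, 0]))


def jackknife_cov(estimate: np.ndarray, loo: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Covariance matrix of a vector estimate from delete-one-block estimates.

    Parameters
    ----------
    estimate : (D,) full-data estimate
    loo : (B, D) delete-one-block estimates
    weights : (B,) non-negative block weights (e.g. SNP counts)
    """
    estimate = np.asarray(estimate, dtype=float)
    loo = np.asarray(loo, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    loo = loo[keep]
    weights = weights[keep]
    B = len(weights)
    if B < 2:
        return np.full((len(estimate), len(estimate)), np.nan)
    W = weights.sum()
    h = W / weights  # (B,)
    theta_j = B * estimate - ((1.0 - weights / W)[:, None] * loo).sum(axis=0)
    tau = h[:, None] * estimate[None, :] - (h - 1.0)[:, None] * loo  # pseudovalues
    dev = tau - theta_j[None, :]
    scaled = dev / np.sqrt((h - 1.0))[:, None]
    return scaled.T @ scaled / B
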