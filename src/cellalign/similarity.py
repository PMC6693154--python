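"""Perplexity-calibrated Gaussian transition kernels in expression space.

For each cell i within one condition (or one training mini-batch of one
condition) the kernel row is

    Q[i, k] = exp(-0.5 ||x_i - x_k||^2 / sigma_i^2) / Z_i,   k != i,

with a per-cell bandwidth sigma_i^2 chosen by binary search so that the
row's perplexity 2^H(Q[i, .]) hits a common target (default 30) — the same
calibration used by tSNE.  The diagonal is exactly zero: a cell is never its
own neighbor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

#: binary-search bounds and defaults for the bandwidth calibration
SIGMA_SQ_LO = 1e-12
SIGMA_SQ_HI = 1e12
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 50


@dataclass
class ConditionKernel:
    """Row-stochastic transition matrix of one condition / mini-batch."""

    probs: np.ndarray          # n x n, zero diagonal, rows sum to 1
    sigma_sq: np.ndarray       # per-cell bandwidth
    perplexity_target: float
    cell_index: list

    def row_perplexities(self) -> np.ndarray:
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 ** (-plogp.sum(axis=1))


def squared_distances(X: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise squared Euclidean distances, zero diagonal."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    D2 = cdist(X, X, "sqeuclidean")
    D2 = 0.5 * (D2 + D2.T)
    np.fill_diagonal(D2, 0.0)
    return np.maximum(D2, 0.0)


def _q_rows(D2_off: np.ndarray, sigma_sq: np.ndarray) -> np.ndarray:
    """Normalized Gaussian rows for an n x (n-1) matrix of off-diagonal
    squared distances; shifted by the per-row minimum for stability."""
    shifted = D2_off - D2_off.min(axis=1, keepdims=True)
    w = np.exp(-0.5 * shifted / sigma_sq[:, None])
    return w / w.sum(axis=1, keepdims=True)


def _row_log2_perplexity(q: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log2(q), 0.0)
    return -plogp.sum(axis=1)  # H in bits; perplexity = 2^H


def _calibrate(D2_off: np.ndarray, perplexity: float, tol: float, max_iter: int):
    """Vectorized geometric bisection on sigma^2 for every row at once."""
    n_rows, n_other = D2_off.shape
    if perplexity >= n_other + 1:
        warnings.warn(
            f"perplexity {perplexity} unreachable for neighborhood of {n_other}; "
            f"clamping to {n_other}"
        )
        perplexity = float(n_other)
    target = np.log2(perplexity)
    lo = np.full(n_rows, SIGMA_SQ_LO)
    hi = np.full(n_rows, SIGMA_SQ_HI)
    sigma_sq = np.sqrt(lo * hi)
    q = _q_rows(D2_off, sigma_sq)
    active = np.arange(n_rows)
    for _ in range(max_iter):
        err = _row_log2_perplexity(q[active]) - target
        done = np.abs(err) <= tol
        active = active[~done]
        if active.size == 0:
            break
        err = err[~done]
        # perplexity is monotone increasing in sigma^2
        hi[active] = np.where(err > 0, sigma_sq[active], hi[active])
        lo[active] = np.where(err < 0, sigma_sq[active], lo[active])
        sigma_sq[active] = np.sqrt(lo[active] * hi[active])
        q[active] = _q_rows(D2_off[active], sigma_sq[active])
    # degenerate rows (all distances equal): Gaussian row is uniform for any
    # sigma — a well-defined limit, leave as-is
    return sigma_sq, q


def calibrate_bandwidth(d2_row: np.ndarray, perplexity: float,
                        tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER):
    """Calibrate one cell's bandwidth.

    ``d2_row`` holds the n-1 squared distances to the other cells.  Returns
    ``(sigma_sq, q_row)`` where ``q_row`` is the normalized Gaussian kernel
    over the other cells.
    """
    d2_row = np.asarray(d2_row, dtype=np.float64)
    if not np.all(np.isfinite(d2_row)):
        raise ValueError("non-finite distances")
    sigma_sq, q = _calibrate(d2_row[None, :], perplexity, tol, max_iter)
    return float(sigma_sq[0]), q[0]


def expression_transition_matrix(X: np.ndarray, perplexity: float = 30.0,
                                 tol: float = DEFAULT_TOL,
                                 max_iter: int = DEFAULT_MAX_ITER,
                                 cell_index=None) -> ConditionKernel:
    """Assemble the full zero-diagonal, row-stochastic kernel Q for one
    condition or mini-batch."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    D2 = squared_distances(X)
    off = ~np.eye(n, dtype=bool)
    D2_off = D2[off].reshape(n, n - 1)
    degenerate = D2_off.max(axis=1) <= 1e-300
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cell(s) identical to all others; "
            "using uniform kernel rows for them"
        )
    sigma_sq, q_off = _calibrate(D2_off, perplexity, tol, max_iter)
    probs = np.zeros((n, n))
    probs[off] = q_off.ravel()
    if cell_index is None:
        cell_index = list(range(n))
    return ConditionKernel(
        probs=probs, sigma_sq=sigma_sq,
        perplexity_target=float(min(perplexity, n - 1)),
        cell_index=list(cell_index),
    )
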