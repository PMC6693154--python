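"""The preprocessing chain: TP10K -> log1p -> scale/center -> HVG -> PCA.

Conventions fixed here so results are exactly reproducible:

* z-scoring uses the population (divide-by-n) standard deviation;
* variable-gene variance is ranked on the log layer, per condition;
* PCA is an exact SVD of the pooled centered matrix, with each component's
  sign fixed so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import ExpressionDataset


def tp10k_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each cell so its counts sum to 10,000."""
    if ds.layer != "counts":
        raise ValueError(f"tp10k_normalize expects counts layer, got {ds.layer}")
    totals = ds.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total counts: {[ds.cell_ids[i] for i in zero[:5]]}")
    values = ds.values * (10_000.0 / totals)[:, None]
    return ds.with_values(values, "tp10k")


def log1p_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Natural log of (1 + value)."""
    if ds.layer != "tp10k":
        raise ValueError(f"log1p_transform expects tp10k layer, got {ds.layer}")
    if np.any(ds.values < 0):
        raise ValueError("negative values in tp10k layer")
    return ds.with_values(np.log1p(ds.values), "log")


def scale_center(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-feature z-score (population sd); constant features become zero.

    The log-layer matrix is stashed in ``extras['log']`` so that
    variable-gene selection can still rank on log-scale variance afterwards.
    Applying this twice is a no-op on nonconstant features (idempotence).
    """
    if ds.layer not in ("log", "scaled"):
        raise ValueError(f"scale_center expects log or scaled layer, got {ds.layer}")
    X = ds.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population (ddof=0)
    out = np.zeros_like(X)
    nonconst = sd > 1e-12
    out[:, nonconst] = (X[:, nonconst] - mean[nonconst]) / sd[nonconst]
    extras = dict(ds.extras)
    if ds.layer == "log":
        extras["log"] = X.copy()
    return ds.with_values(out, "scaled", extras=extras)


def select_variable_genes(ds: ExpressionDataset, per_condition_top_k: int) -> ExpressionDataset:
    """Keep the union over conditions of each condition's top-k most variable
    genes, ranked on log-layer variance; input feature order is preserved."""
    if ds.layer not in ("log", "scaled"):
        raise ValueError(f"select_variable_genes expects log or scaled layer, got {ds.layer}")
    if per_condition_top_k < 1:
        raise ValueError("per_condition_top_k must be >= 1")
    g = ds.n_features
    k = per_condition_top_k
    if k > g:
        warnings.warn(f"top_k={k} exceeds {g} features; keeping all")
        k = g
    if ds.layer == "log":
        ranking_matrix = ds.values
    elif "log" in ds.extras:
        ranking_matrix = ds.extras["log"]
    else:
        warnings.warn("no stashed log layer; ranking variance on the scaled matrix")
        ranking_matrix = ds.values
    keep = np.zeros(g, dtype=bool)
    for cond in ds.conditions:
        var = ranking_matrix[ds.condition_mask(cond)].var(axis=0)
        top = np.argsort(-var, kind="stable")[:k]
        keep[top] = True
    idx = np.flatnonzero(keep)
    extras = dict(ds.extras)
    if "log" in extras:
        extras["log"] = extras["log"][:, idx]
    out = ds.with_values(
        ds.values[:, idx], ds.layer, feature_ids=[ds.feature_ids[i] for i in idx],
        extras=extras,
    )
    return out


@dataclass
class PCABasis:
    """Projection learned by :func:`pca_reduce`; lets new (e.g. perturbed)
    gene-space profiles be mapped into the same score space."""

    loadings: np.ndarray  # features x components
    mean: np.ndarray      # per-feature mean subtracted before projection
    explained_variance: np.ndarray
    feature_ids: list

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) @ self.loadings


def pca_reduce(ds: ExpressionDataset, n_components: int, seed: int = 0):
    """Exact-SVD PCA of the pooled scaled matrix.

    Returns the score-space dataset (layer ``pca``, gene-space matrix stashed
    in ``extras``) and the :class:`PCABasis`.  ``seed`` is accepted for
    interface symmetry; the exact solver is deterministic.
    """
    if ds.layer != "scaled":
        raise ValueError(f"pca_reduce expects scaled layer, got {ds.layer}")
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if n_components > min(ds.n_cells, ds.n_features):
        raise ValueError("n_components exceeds matrix rank bound")
    X = ds.values
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    basis = PCABasis(
        loadings=Vt.T,
        mean=mean,
        explained_variance=S**2 / max(ds.n_cells - 1, 1),
        feature_ids=list(ds.feature_ids),
    )
    extras = dict(ds.extras)
    extras["expression"] = X.copy()
    extras["expression_feature_ids"] = list(ds.feature_ids)
    out = ds.with_values(
        scores, "pca", feature_ids=[f"PC{j + 1}" for j in range(n_components)],
        extras=extras,
    )
    return out, basis


def standard_pipeline(ds: ExpressionDataset, hvg_k: int | None = None,
                      pca_dims: int | None = None, seed: int = 0):
    """counts -> TP10K -> log -> (HVG) -> scale/center -> (PCA).

    Returns ``(dataset, basis)`` where ``basis`` is None without PCA.
    """
    out = log1p_transform(tp10k_normalize(ds))
    if hvg_k is not None:
        out = select_variable_genes(out, hvg_k)
    out = scale_center(out)
    basis = None
    if pca_dims is not None:
        out, basis = pca_reduce(out, pca_dims, seed=seed)
    return out, basis
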