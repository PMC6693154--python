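"""In-silico gene-set perturbation of the alignment embedding.

Robust common markers are genes that mark a cell type in *every* condition
(rank-sum one-vs-rest, BH-corrected, expanded by tight correlation, then
intersected across conditions).  Zeroing a gene set and re-embedding all
cells measures how much the alignment relies on it; significance comes from
expression-matched random control sets and a permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .aligner import AlignmentModel, embed_cells
from .dataset import UNLABELED, ExpressionDataset
from .preprocess import PCABasis


def robust_markers(ds: ExpressionDataset, labels=None, alpha: float = 0.05,
                   corr_threshold: float = 0.9) -> dict:
    """Per-cell-type marker sets that replicate across conditions.

    Within each condition: for every cell type, a one-sided (greater)
    Wilcoxon rank-sum test per gene against all other cells, BH correction,
    keep adjusted p < ``alpha``; then add genes whose within-condition
    Pearson correlation with any marker exceeds ``corr_threshold``.  The
    final set per type is the intersection across conditions.
    """
    labels = np.asarray(labels if labels is not None else ds.type_of, dtype=object)
    types = sorted({t for t in labels if t != UNLABELED})
    per_condition: dict = {}
    for cond in ds.conditions:
        cmask = ds.condition_mask(cond)
        X = ds.values[cmask]
        lab = labels[cmask]
        corr = np.corrcoef(X, rowvar=False)
        sets = {}
        for t in types:
            tmask = lab == t
            if tmask.sum() < 2 or (~tmask).sum() < 2:
                warnings.warn(f"type {t!r} too small in condition {cond!r}; skipped")
                continue
            stat = mannwhitneyu(X[tmask], X[~tmask], alternative="greater", axis=0)
            ok = np.isfinite(stat.pvalue)
            reject = np.zeros(ds.n_features, dtype=bool)
            if ok.any():
                adj = multipletests(stat.pvalue[ok], method="fdr_bh")[1]
                reject[ok] = adj < alpha
            markers = np.flatnonzero(reject)
            if markers.size:
                correlated = np.flatnonzero(
                    np.nanmax(corr[:, markers], axis=1) > corr_threshold
                )
                markers = np.union1d(markers, correlated)
            sets[t] = set(markers)
        per_condition[cond] = sets
    out = {}
    for t in types:
        present = [per_condition[c][t] for c in ds.conditions
                   if t in per_condition[c]]
        if len(present) < len(ds.conditions):
            continue
        common = set.intersection(*present) if present else set()
        out[t] = sorted(ds.feature_ids[i] for i in common)
    return out


def matched_control_sets(ds: ExpressionDataset, target_set, n_sets: int = 10_000,
                         n_bins: int = 5, seed: int = 0) -> list:
    """Random gene sets matched to ``target_set`` for size and expression.

    Genes are split into ``n_bins`` approximately equal-sized bins by mean
    expression over all cells; each control set draws, without replacement
    within each bin, the same per-bin counts as the target.
    """
    target_set = list(target_set)
    if not target_set:
        raise ValueError("target_set is empty")
    index = {g: i for i, g in enumerate(ds.feature_ids)}
    missing = [g for g in target_set if g not in index]
    if missing:
        raise ValueError(f"target genes absent from dataset: {missing[:5]}")
    target_idx = np.array([index[g] for g in target_set])
    mean_expr = ds.values.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(ds.n_features, dtype=int)
    for b, genes in enumerate(bins):
        bin_of[genes] = b
    need = np.bincount(bin_of[target_idx], minlength=n_bins)
    for b in range(n_bins):
        if need[b] > len(bins[b]):
            raise ValueError(f"bin {b} has {len(bins[b])} genes but {need[b]} required")
    rng = np.random.default_rng(seed)
    features = np.asarray(ds.feature_ids, dtype=object)
    out = []
    for _ in range(n_sets):
        picked = [rng.choice(bins[b], size=need[b], replace=False)
                  for b in range(n_bins) if need[b] > 0]
        out.append(list(features[np.concatenate(picked)]))
    return out


def perturb_embedding_shift(model: AlignmentModel, ds: ExpressionDataset,
                            gene_set, projection: PCABasis | None = None):
    """Per-cell embedding displacement after zeroing a gene set.

    ``ds`` is a gene-space dataset.  For models trained on PCA scores, pass
    the stored :class:`PCABasis`; the zeroed expression is re-projected
    through it before encoding.  Returns ``(median_shift, max_shift)``.
    """
    gene_set = list(gene_set)
    index = {g: i for i, g in enumerate(ds.feature_ids)}
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"gene(s) not in dataset: {missing[:5]}")
    X = ds.values
    Xz = X.copy()
    if gene_set:
        Xz[:, [index[g] for g in gene_set]] = 0.0
    if projection is not None:
        E0 = embed_cells(model, projection.project(X))
        E1 = embed_cells(model, projection.project(Xz))
    else:
        E0 = embed_cells(model, X)
        E1 = embed_cells(model, Xz)
    shifts = np.linalg.norm(E0 - E1, axis=1)
    return float(np.median(shifts)), float(shifts.max())


def perturbation_pvalue(observed_median: float, null_medians) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + n)."""
    null_medians = np.asarray(null_medians, dtype=np.float64)
    if null_medians.size == 0:
        raise ValueError("empty null")
    return float((1 + np.sum(null_medians >= observed_median)) /
                 (1 + null_medians.size))


@dataclass
class GeneSetPerturbationResult:
    gene_set: list
    median_shift: float
    max_shift: float
    null_medians: np.ndarray
    p_value: float
    fold_vs_null: float


def gene_set_perturbation_test(model: AlignmentModel, ds: ExpressionDataset,
                               gene_set, *, n_sets: int = 10_000,
                               n_bins: int = 5, seed: int = 0,
                               projection: PCABasis | None = None
                               ) -> GeneSetPerturbationResult:
    """Full perturbation analysis: observed shift, matched-control null,
    permutation p-value and fold enrichment of the median shift."""
    med, mx = perturb_embedding_shift(model, ds, gene_set, projection=projection)
    controls = matched_control_sets(ds, gene_set, n_sets=n_sets, n_bins=n_bins,
                                    seed=seed)
    null = np.array([
        perturb_embedding_shift(model, ds, c, projection=projection)[0]
        for c in controls
    ])
    p = perturbation_pvalue(med, null)
    denom = float(np.median(null))
    fold = float(med / denom) if denom > 0 else float("inf")
    return GeneSetPerturbationResult(
        gene_set=list(gene_set), median_shift=med, max_shift=mx,
        null_medians=null, p_value=p, fold_vs_null=fold,
    )
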