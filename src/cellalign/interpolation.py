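"""Decoders from alignment space back to expression, and state-variance maps.

One decoder is trained per condition, on that condition's cells only, to
reconstruct gene-space expression from the frozen encoder's embeddings.
Applying every decoder to every cell "interpolates" each cell into every
condition — simulating sequencing the same cell under each condition.  The
across-condition variance of those interpolated profiles (cells x genes) is
the state-variance map; with two conditions it reduces to a per-cell paired
differential-expression map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aligner import AlignmentModel, embed_cells
from .autodiff import Tensor
from .dataset import ExpressionDataset
from .nn import MLP, Adam


@dataclass
class DecoderModel:
    """Per-condition decoder; architecture mirrors the encoder in reverse
    (K -> reversed hidden sizes -> gene dimension, linear output)."""

    condition: str
    net: MLP
    feature_ids: list
    seed: int
    loss_trace: list = field(default_factory=list)

    def decode(self, E: np.ndarray) -> np.ndarray:
        return self.net(np.asarray(E), training=False).data


def train_decoder(model: AlignmentModel, ds: ExpressionDataset, condition: str,
                  *, max_steps: int = 30_000, learning_rate: float = 1e-4,
                  batch_size: int | None = None, seed: int = 0) -> DecoderModel:
    """Train the decoder for one condition by MSE on (embedding -> expression).

    The encoder is frozen; targets are always the gene-space expression
    layer, even when the encoder consumed PCA scores.
    """
    if condition not in ds.conditions:
        raise ValueError(f"condition {condition!r} not present")
    mask = ds.condition_mask(condition)
    E = embed_cells(model, ds.values[mask])
    X = ds.expression_matrix()[mask]
    feature_ids = ds.expression_feature_ids()

    cfg = model.config
    if batch_size is None:
        batch_size = cfg.batch_size
    ss = np.random.SeedSequence([int(seed), 4])
    init_seed, batch_seed, dropout_seed = ss.spawn(3)
    net = MLP(
        E.shape[1], tuple(reversed(cfg.hidden_sizes)), X.shape[1],
        np.random.default_rng(init_seed),
        dropout_rate=cfg.dropout_rate, batch_norm=cfg.batch_norm,
    )
    dec = DecoderModel(condition=condition, net=net, feature_ids=feature_ids,
                       seed=seed)
    rng_batch = np.random.default_rng(batch_seed)
    rng_dropout = np.random.default_rng(dropout_seed)
    opt = Adam(net.parameters(), lr=learning_rate)
    n = E.shape[0]
    b = min(batch_size, n)
    pool, pos = rng_batch.permutation(n), 0
    for step in range(max_steps):
        if pos + b > n:
            pool, pos = rng_batch.permutation(n), 0
        idx = pool[pos:pos + b]
        pos += b
        opt.zero_grad()
        pred = net(E[idx], training=True, rng=rng_dropout)
        diff = pred - Tensor(X[idx])
        loss = (diff * diff).mean()
        loss.backward()
        opt.step()
        dec.loss_trace.append({"step": step, "mse": float(loss.data)})
    return dec


def train_all_decoders(model: AlignmentModel, ds: ExpressionDataset,
                       **kwargs) -> dict:
    return {c: train_decoder(model, ds, c, **kwargs) for c in ds.conditions}


def interpolate_expression(decoders: dict, model: AlignmentModel,
                           ds: ExpressionDataset) -> dict:
    """Decode every cell (from any origin) into every condition's expression
    space.  Returns ``{condition: n_cells x n_genes matrix}``."""
    missing = [c for c in ds.conditions if c not in decoders]
    if missing:
        raise ValueError(f"no decoder for condition(s) {missing}")
    E = embed_cells(model, ds)
    return {c: decoders[c].decode(E) for c in decoders}


@dataclass
class StateVarianceMap:
    """Across-condition variance of interpolated expression, per cell/gene."""

    variance: np.ndarray             # cells x genes, sample variance (n-1)
    per_cell_score: np.ndarray       # row means of ``variance``
    condition_order: list
    paired_diff: np.ndarray | None = None  # second minus first, 2 conditions


def state_variance_map(interpolations: dict) -> StateVarianceMap:
    """Entrywise sample variance across conditions; with exactly two
    conditions also the paired difference (lexicographically second minus
    first)."""
    conds = sorted(interpolations)
    if len(conds) < 2:
        raise ValueError("state variance map needs at least 2 conditions")
    stack = np.stack([np.asarray(interpolations[c]) for c in conds], axis=0)
    if len({m.shape for m in stack}) > 1:
        raise ValueError("interpolated matrices differ in shape")
    variance = stack.var(axis=0, ddof=1)
    paired = None
    if len(conds) == 2:
        paired = stack[1] - stack[0]
    return StateVarianceMap(
        variance=variance,
        per_cell_score=variance.mean(axis=1),
        condition_order=conds,
        paired_diff=paired,
    )
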