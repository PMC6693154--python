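"""Alignment of cells across conditions with a round-trip random-walk loss.

A single encoder network maps cells from every condition into a shared
K-dimensional alignment space.  For each pair of conditions (s, t) the
embedding dot products define cross-condition walk probabilities

    P_fwd[i, j] = softmax_j <e_i^s, e_j^t>,   P_bwd[j, i] = softmax_i <e_j^t, e_i^s>,

and the length-two round trip P^s = P_fwd @ P_bwd.  Training minimizes the
cross-entropy between P^s and the expression-space kernel Q^s of the
originating condition (and symmetrically for t), so that (a) cells must
walk through the *other* condition — forcing the conditions to overlap in
the embedding — while (b) the within-condition neighborhood structure of
the expression data is preserved.  Q has zero diagonal ("return to a
different cell"), so the self-return mass of P^s receives no target
probability and is implicitly penalized through row normalization.

Optionally, a linear classifier head on the embedding adds a cross-entropy
term over whatever subset of cells carries type labels (semi-supervised
alignment).  A same-architecture shared autoencoder is provided as the
reconstruction-loss baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, log_softmax_rows, softmax_rows
from .dataset import UNLABELED, ExpressionDataset
from .nn import MLP, Adam, Linear
from .similarity import ConditionKernel, expression_transition_matrix

LOG_FLOOR = 1e-30


# ---------------------------------------------------------------------------
# configuration and model containers
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Architecture and optimization settings.

    ``embedding_dim=None`` resolves at training time to 32 for two
    conditions and 64 for three or more.
    """

    hidden_sizes: tuple = (512, 256, 128)
    embedding_dim: int | None = None
    dropout_rate: float = 0.30
    batch_norm: bool = True
    ridge: float = 1e-4
    learning_rate: float = 1e-4
    max_steps: int = 15_000
    batch_size: int = 150
    perplexity: float = 30.0
    alpha: float = 1.0
    beta: float = 1.0
    mode: str = "pairwise"  # pairwise | all_pairs | reference
    reference_condition: str | None = None
    supervised_through_encoder: bool = True
    seed: int = 0

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.mode not in ("pairwise", "all_pairs", "reference"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("dropout_rate",):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("learning_rate", "max_steps", "batch_size", "perplexity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode == "reference" and self.reference_condition is None:
            raise ValueError("reference mode needs reference_condition")

    def resolved_embedding_dim(self, n_conditions: int) -> int:
        if self.embedding_dim is not None:
            return int(self.embedding_dim)
        return 64 if n_conditions >= 3 else 32


@dataclass
class LabelMatrix:
    """n x C one-hot indicator; all-zero rows mark unlabeled cells."""

    A: np.ndarray
    class_names: list

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        sums = self.A.sum(axis=1)
        if not np.all((np.abs(sums) < 1e-12) | (np.abs(sums - 1) < 1e-12)):
            raise ValueError("each LabelMatrix row must sum to 0 or 1")

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.A.sum(axis=1) > 0.5

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())


def label_matrix_from_types(ds: ExpressionDataset, class_names=None,
                            mask=None) -> LabelMatrix:
    """Build a LabelMatrix from ``ds.type_of``; the unlabeled sentinel maps
    to an all-zero row.  ``mask`` (boolean per cell) can hide labels, e.g.
    to label only one condition for semi-supervised training."""
    types = ds.type_of
    if class_names is None:
        class_names = sorted({t for t in types if t != UNLABELED})
    index = {c: j for j, c in enumerate(class_names)}
    A = np.zeros((ds.n_cells, len(class_names)))
    for i, t in enumerate(types):
        if t in index and (mask is None or mask[i]):
            A[i, index[t]] = 1.0
    return LabelMatrix(A=A, class_names=list(class_names))


@dataclass
class TransitionSet:
    """Embedding-space walk matrices for one pair of conditions."""

    p_fwd: np.ndarray     # m x n
    p_bwd: np.ndarray     # n x m
    p_round_s: np.ndarray  # m x m  (= p_fwd @ p_bwd)
    p_round_t: np.ndarray  # n x n  (= p_bwd @ p_fwd)


@dataclass
class AlignmentModel:
    encoder: MLP
    config: EncoderConfig
    input_dim: int
    head: Linear | None = None
    class_names: list | None = None
    loss_trace: list = field(default_factory=list)
    conditions: list | None = None

    def save(self, path):
        state = {f"enc_{k}": v for k, v in self.encoder.state_arrays().items()}
        if self.head is not None:
            state["head_W"] = self.head.W.data
            state["head_b"] = self.head.b.data
        meta = {
            "config": asdict(self.config),
            "input_dim": self.input_dim,
            "class_names": self.class_names,
            "conditions": self.conditions,
        }
        state["meta_json"] = np.array(json.dumps(meta))
        if self.loss_trace:
            keys = sorted(self.loss_trace[0])
            state["trace_keys"] = np.array(keys)
            state["trace"] = np.array(
                [[row[k] for k in keys] for row in self.loss_trace]
            )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "AlignmentModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta_json"]))
            config = EncoderConfig(**meta["config"])
            n_cond = len(meta["conditions"] or [1, 2])
            model = build_encoder(meta["input_dim"], config, n_conditions=n_cond)
            model.encoder.load_state_arrays(data, prefix="enc_")
            if "head_W" in data:
                rng = np.random.default_rng(0)
                head = Linear(data["head_W"].shape[0], data["head_W"].shape[1], rng)
                head.W.data = np.array(data["head_W"])
                head.b.data = np.array(data["head_b"])
                model.head = head
            model.class_names = meta["class_names"]
            model.conditions = meta["conditions"]
            if "trace" in data:
                keys = [str(k) for k in data["trace_keys"]]
                model.loss_trace = [
                    dict(zip(keys, row)) for row in data["trace"]
                ]
        return model


def build_encoder(input_dim: int, config: EncoderConfig,
                  n_conditions: int = 2) -> AlignmentModel:
    """Fresh Xavier-initialized encoder; deterministic given ``config.seed``."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    encoder = MLP(
        input_dim, config.hidden_sizes,
        config.resolved_embedding_dim(n_conditions),
        rng, dropout_rate=config.dropout_rate, batch_norm=config.batch_norm,
    )
    return AlignmentModel(encoder=encoder, config=config, input_dim=input_dim)


# ---------------------------------------------------------------------------
# objective pieces (numpy inspection API)
# ---------------------------------------------------------------------------

def _np_softmax_rows(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def embedding_transitions(E_s: np.ndarray, E_t: np.ndarray) -> TransitionSet:
    """Walk matrices from embedding dot products (numpy, inference use)."""
    E_s = np.atleast_2d(np.asarray(E_s, dtype=np.float64))
    E_t = np.atleast_2d(np.asarray(E_t, dtype=np.float64))
    if E_s.shape[1] != E_t.shape[1]:
        raise ValueError("embedding dimensions differ")
    logits = E_s @ E_t.T
    p_fwd = _np_softmax_rows(logits)
    p_bwd = _np_softmax_rows(logits.T)
    return TransitionSet(
        p_fwd=p_fwd, p_bwd=p_bwd,
        p_round_s=p_fwd @ p_bwd, p_round_t=p_bwd @ p_fwd,
    )


def _cross_entropy_rows(Q: np.ndarray, P: np.ndarray) -> float:
    """Mean over rows of -sum_k Q[i,k] log P[i,k], log floored at 1e-30."""
    return float(-(Q * np.log(np.maximum(P, LOG_FLOOR))).sum() / Q.shape[0])


def walker_objective(kernel_s: ConditionKernel, kernel_t: ConditionKernel,
                     trans: TransitionSet):
    """Round-trip walk loss for one condition pair, with per-term breakdown."""
    term_s = _cross_entropy_rows(kernel_s.probs, trans.p_round_s)
    term_t = _cross_entropy_rows(kernel_t.probs, trans.p_round_t)
    return term_s + term_t, {"walker_s": term_s, "walker_t": term_t}


def supervised_objective(A: np.ndarray | LabelMatrix, logits: np.ndarray) -> float:
    """Mean softmax cross-entropy over labeled cells only; 0 if none."""
    if isinstance(A, LabelMatrix):
        A = A.A
    A = np.asarray(A, dtype=np.float64)
    logits = np.asarray(logits, dtype=np.float64)
    labeled = A.sum(axis=1) > 0.5
    if not labeled.any():
        return 0.0
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(A[labeled] * logp[labeled]).sum() / labeled.sum())


def _ordered_pairs(conditions, mode, reference):
    conds = list(conditions)
    if mode == "pairwise":
        if len(conds) != 2:
            raise ValueError("pairwise mode requires exactly 2 conditions")
        return [(conds[0], conds[1]), (conds[1], conds[0])]
    if mode == "all_pairs":
        return [(a, b) for a in conds for b in conds if a != b]
    if reference not in conds:
        raise ValueError(f"reference condition {reference!r} not in data")
    return [(reference, l) for l in conds if l != reference]


# ---------------------------------------------------------------------------
# autodiff loss
# ---------------------------------------------------------------------------

def _batch_loss(model: AlignmentModel, X_by_cond: dict, A_by_cond: dict | None,
                config: EncoderConfig, pairs, *, training: bool,
                rng: np.random.Generator | None = None,
                kernels: dict | None = None):
    """Total objective on one set of per-condition batches, as an autodiff
    Tensor plus a float breakdown.

    walker + supervised terms are weighted by alpha and beta; the ridge term
    covers affine weight matrices only (no biases, no batch-norm params).
    """
    E = {}
    for cond, X in X_by_cond.items():
        E[cond] = model.encoder(X, training=training, rng=rng)

    if kernels is None:
        kernels = {
            cond: expression_transition_matrix(X, perplexity=config.perplexity)
            for cond, X in X_by_cond.items()
        }

    walker = Tensor(0.0)
    for a, b in pairs:
        P_ab = softmax_rows(E[a] @ E[b].T)
        P_ba = softmax_rows(E[b] @ E[a].T)
        P_round = P_ab @ P_ba
        m_a = X_by_cond[a].shape[0]
        Q_a = Tensor(kernels[a].probs)
        walker = walker + -(Q_a * P_round.clip_min(LOG_FLOOR).log()).sum() * (1.0 / m_a)

    supervised = Tensor(0.0)
    n_labeled = 0
    if model.head is not None and A_by_cond is not None:
        for cond, A in A_by_cond.items():
            labeled = A.sum(axis=1) > 0.5
            n_labeled += int(labeled.sum())
        if n_labeled > 0:
            for cond, A in A_by_cond.items():
                if A.sum() == 0:
                    continue
                emb = E[cond]
                if not config.supervised_through_encoder:
                    emb = Tensor(emb.data)  # detach
                logp = log_softmax_rows(model.head(emb))
                supervised = supervised + -(Tensor(A) * logp).sum() * (1.0 / n_labeled)

    ridge = Tensor(0.0)
    weight_mats = model.encoder.weight_matrices()
    if model.head is not None:
        weight_mats = weight_mats + model.head.weight_matrices()
    for W in weight_mats:
        ridge = ridge + (W * W).sum()

    total = config.alpha * walker + config.beta * supervised + config.ridge * ridge
    breakdown = {
        "walker": float(walker.data),
        "supervised": float(supervised.data),
        "ridge": float(ridge.data),
        "total": float(total.data),
    }
    return total, breakdown


def total_objective(model: AlignmentModel, X_by_cond: dict,
                    labels_by_cond: dict | None = None,
                    kernels: dict | None = None):
    """Deterministic (inference-mode) evaluation of the full objective.

    Returns ``(total, breakdown)`` where breakdown holds the walker,
    supervised and ridge components.
    """
    config = model.config
    pairs = _ordered_pairs(sorted(X_by_cond), config.mode, config.reference_condition)
    total, breakdown = _batch_loss(
        model, X_by_cond, labels_by_cond, config, pairs,
        training=False, kernels=kernels,
    )
    return breakdown["total"], breakdown


def objective_gradient(model: AlignmentModel, X_by_cond: dict,
                       labels_by_cond: dict | None = None):
    """Backprop gradient of the inference-mode objective, flattened over all
    trainable parameters (for gradient checking)."""
    config = model.config
    pairs = _ordered_pairs(sorted(X_by_cond), config.mode, config.reference_condition)
    params = model.encoder.parameters()
    if model.head is not None:
        params = params + model.head.parameters()
    for p in params:
        p.grad = None
    total, _ = _batch_loss(model, X_by_cond, labels_by_cond, config, pairs,
                           training=False)
    total.backward()
    flat = np.concatenate([
        (p.grad if p.grad is not None else np.zeros_like(p.data)).ravel()
        for p in params
    ])
    return float(total.data), flat, params


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _EpochSampler:
    """Uniform mini-batches without replacement within an epoch; reshuffles
    when fewer than a full batch remains."""

    def __init__(self, indices: np.ndarray, batch_size: int,
                 rng: np.random.Generator, condition_name=""):
        self.indices = np.asarray(indices)
        self.batch_size = min(batch_size, len(self.indices))
        if len(self.indices) < batch_size:
            warnings.warn(
                f"condition {condition_name!r} has {len(self.indices)} cells "
                f"< batch size {batch_size}; using the full condition per step"
            )
        self.rng = rng
        self._pool = rng.permutation(self.indices)
        self._pos = 0

    def draw(self) -> np.ndarray:
        if self._pos + self.batch_size > len(self._pool):
            self._pool = self.rng.permutation(self.indices)
            self._pos = 0
        batch = self._pool[self._pos:self._pos + self.batch_size]
        self._pos += self.batch_size
        return batch


def _training_rngs(seed: int):
    ss = np.random.SeedSequence([int(seed), 1])
    batch_seed, dropout_seed = ss.spawn(2)
    return np.random.default_rng(batch_seed), np.random.default_rng(dropout_seed)


def train_alignment(ds: ExpressionDataset, labels: LabelMatrix | None,
                    config: EncoderConfig) -> AlignmentModel:
    """Train the encoder with the walker objective (plus classifier terms if
    a LabelMatrix with any labeled cell is supplied).

    Per step, an independent mini-batch is drawn from every condition, the
    expression kernels Q are calibrated on those batches, and the walk terms
    for every ordered condition pair dictated by ``config.mode`` are summed.
    Fully deterministic given ``config.seed``.
    """
    conds = ds.conditions
    if len(conds) < 2:
        raise ValueError("alignment requires at least 2 conditions")
    if config.mode == "pairwise" and len(conds) > 2:
        raise ValueError("pairwise mode cannot align more than 2 conditions; "
                         "use all_pairs or reference")
    pairs = _ordered_pairs(conds, config.mode, config.reference_condition)

    model = build_encoder(ds.n_features, config, n_conditions=len(conds))
    model.conditions = conds
    params = model.encoder.parameters()
    if labels is not None and labels.n_labeled > 0:
        rng_head = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        model.head = Linear(
            config.resolved_embedding_dim(len(conds)), len(labels.class_names),
            rng_head,
        )
        model.class_names = list(labels.class_names)
        params = params + model.head.parameters()

    rng_batch, rng_dropout = _training_rngs(config.seed)
    samplers = {
        c: _EpochSampler(np.flatnonzero(ds.condition_mask(c)), config.batch_size,
                         rng_batch, condition_name=c)
        for c in conds
    }
    opt = Adam(params, lr=config.learning_rate)

    for step in range(config.max_steps):
        idx = {c: samplers[c].draw() for c in conds}
        X = {c: ds.values[idx[c]] for c in conds}
        A = None
        if model.head is not None:
            A = {c: labels.A[idx[c]] for c in conds}
        opt.zero_grad()
        total, breakdown = _batch_loss(
            model, X, A, config, pairs, training=True, rng=rng_dropout,
        )
        total.backward()
        opt.step()
        breakdown["step"] = step
        model.loss_trace.append(breakdown)
    return model


def embed_cells(model: AlignmentModel, ds: ExpressionDataset | np.ndarray) -> np.ndarray:
    """Inference-mode forward pass: dropout off, running batch-norm stats."""
    X = ds.values if isinstance(ds, ExpressionDataset) else np.asarray(ds)
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"dataset has {X.shape[1]} features, model expects {model.input_dim}"
        )
    return model.encoder(X, training=False).data


# ---------------------------------------------------------------------------
# shared-autoencoder baseline
# ---------------------------------------------------------------------------

def train_shared_autoencoder(ds: ExpressionDataset, config: EncoderConfig):
    """Same encoder architecture and optimizer, but a reconstruction loss:
    one decoder per condition, objective = mean over conditions of per-cell
    MSE (plus the same ridge on weight matrices).  Returns
    ``(AlignmentModel, {condition: MLP decoder})``.
    """
    conds = ds.conditions
    if len(conds) < 2:
        raise ValueError("baseline expects at least 2 conditions")
    model = build_encoder(ds.n_features, config, n_conditions=len(conds))
    model.conditions = conds
    K = config.resolved_embedding_dim(len(conds))
    rng_dec = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    decoders = {
        c: MLP(K, tuple(reversed(config.hidden_sizes)), ds.n_features, rng_dec,
               dropout_rate=config.dropout_rate, batch_norm=config.batch_norm)
        for c in conds
    }
    params = model.encoder.parameters()
    for c in conds:
        params += decoders[c].parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng_batch, rng_dropout = _training_rngs(config.seed)
    samplers = {
        c: _EpochSampler(np.flatnonzero(ds.condition_mask(c)), config.batch_size,
                         rng_batch, condition_name=c)
        for c in conds
    }
    weight_mats = model.encoder.weight_matrices()
    for c in conds:
        weight_mats += decoders[c].weight_matrices()

    for step in range(config.max_steps):
        opt.zero_grad()
        recon = Tensor(0.0)
        for c in conds:
            Xb = ds.values[samplers[c].draw()]
            emb = model.encoder(Xb, training=True, rng=rng_dropout)
            rec = decoders[c](emb, training=True, rng=rng_dropout)
            diff = rec - Tensor(Xb)
            recon = recon + (diff * diff).mean() * (1.0 / len(conds))
        ridge = Tensor(0.0)
        for W in weight_mats:
            ridge = ridge + (W * W).sum()
        total = recon + config.ridge * ridge
        total.backward()
        opt.step()
        model.loss_trace.append({
            "step": step, "total": float(total.data),
            "reconstruction": float(recon.data), "ridge": float(ridge.data),
        })
    return model, decoders
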