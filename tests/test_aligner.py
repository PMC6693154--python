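import numpy as np
import pytest

import cellalign as ca
from cellalign.aligner import _np_softmax_rows, objective_gradient
from cellalign.nn import Linear


def _config(**kw):
    base = dict(hidden_sizes=(8, 4), embedding_dim=2, dropout_rate=0.0,
                batch_norm=True, ridge=1e-3, seed=0)
    base.update(kw)
    return ca.EncoderConfig(**base)


# ---------------------------------------------------------------------------
# encoder construction
# ---------------------------------------------------------------------------

def test_build_encoder_shapes():
    model = ca.build_encoder(10, _config())
    shapes = [lin.W.data.shape for lin, _ in model.encoder.hidden]
    assert shapes == [(10, 8), (8, 4)]
    assert model.encoder.out.W.data.shape == (4, 2)


def test_build_encoder_seed_determinism():
    m1 = ca.build_encoder(6, _config(seed=3))
    m2 = ca.build_encoder(6, _config(seed=3))
    for a, b in zip(m1.encoder.parameters(), m2.encoder.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


def test_empty_hidden_is_single_linear(rng):
    model = ca.build_encoder(5, _config(hidden_sizes=(), batch_norm=False))
    X = rng.normal(size=(4, 5))
    out = ca.embed_cells(model, X)
    expected = X @ model.encoder.out.W.data + model.encoder.out.b.data
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_zero_weights_propagate_bias(rng):
    model = ca.build_encoder(5, _config(hidden_sizes=(3,), batch_norm=False))
    for lin, _ in model.encoder.hidden:
        lin.W.data[:] = 0
        lin.b.data[:] = 1.0
    model.encoder.out.W.data[:] = 0
    model.encoder.out.b.data[:] = 2.5
    out = ca.embed_cells(model, rng.normal(size=(3, 5)))
    np.testing.assert_allclose(out, 2.5)


# ---------------------------------------------------------------------------
# embedding transitions
# ---------------------------------------------------------------------------

def test_transitions_zero_embeddings_uniform():
    trans = ca.embedding_transitions(np.zeros((2, 3)), np.zeros((3, 3)))
    np.testing.assert_allclose(trans.p_fwd, 1 / 3)
    np.testing.assert_allclose(trans.p_bwd, 1 / 2)
    np.testing.assert_allclose(trans.p_round_s, 1 / 2)


def test_transitions_single_cells():
    trans = ca.embedding_transitions(np.array([[1.0, 2.0]]), np.array([[0.5, 0.1]]))
    for M in (trans.p_fwd, trans.p_bwd, trans.p_round_s, trans.p_round_t):
        np.testing.assert_allclose(M, [[1.0]])


def test_round_trip_matches_walk_enumeration(rng):
    E_s, E_t = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
    trans = ca.embedding_transitions(E_s, E_t)
    # explicit two-step walk: sum over intermediate cells j in t
    for i in range(4):
        for k in range(4):
            p = sum(trans.p_fwd[i, j] * trans.p_bwd[j, k] for j in range(3))
            assert trans.p_round_s[i, k] == pytest.approx(p, abs=1e-12)
    np.testing.assert_allclose(trans.p_round_s.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(trans.p_round_t.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _kernel_from_probs(probs):
    n = probs.shape[0]
    return ca.ConditionKernel(probs=probs, sigma_sq=np.ones(n),
                              perplexity_target=2.0, cell_index=list(range(n)))


def test_walker_entropy_lower_bound(rng):
    """When P matches Q off-diagonal exactly, CE equals the entropy of Q."""
    n = 5
    q = rng.uniform(0.1, 1.0, size=(n, n))
    np.fill_diagonal(q, 0)
    q /= q.sum(axis=1, keepdims=True)
    kern = _kernel_from_probs(q)
    trans = ca.TransitionSet(p_fwd=q, p_bwd=q, p_round_s=q, p_round_t=q)
    loss, parts = ca.walker_objective(kern, kern, trans)
    entropy = -(q[q > 0] * np.log(q[q > 0])).sum() / n
    assert loss == pytest.approx(2 * entropy, abs=1e-10)


def test_walker_uniform_includes_diagonal_mass():
    """Uniform Q (off-diag) against uniform P over all m costs log m per row."""
    m = 4
    q = np.full((m, m), 1 / (m - 1))
    np.fill_diagonal(q, 0)
    p = np.full((m, m), 1 / m)
    kern = _kernel_from_probs(q)
    trans = ca.TransitionSet(p_fwd=p, p_bwd=p, p_round_s=p, p_round_t=p)
    loss, _ = ca.walker_objective(kern, kern, trans)
    assert loss == pytest.approx(2 * np.log(m), abs=1e-12)


def test_walker_matches_double_loop(rng):
    m, n = 5, 4
    E_s, E_t = rng.normal(size=(m, 2)), rng.normal(size=(n, 2))
    q_s = rng.uniform(0.1, 1, size=(m, m)); np.fill_diagonal(q_s, 0)
    q_s /= q_s.sum(axis=1, keepdims=True)
    q_t = rng.uniform(0.1, 1, size=(n, n)); np.fill_diagonal(q_t, 0)
    q_t /= q_t.sum(axis=1, keepdims=True)
    trans = ca.embedding_transitions(E_s, E_t)
    loss, _ = ca.walker_objective(_kernel_from_probs(q_s), _kernel_from_probs(q_t), trans)
    naive = 0.0
    for i in range(m):
        for k in range(m):
            if q_s[i, k] > 0:
                naive -= q_s[i, k] * np.log(trans.p_round_s[i, k]) / m
    for j in range(n):
        for k in range(n):
            if q_t[j, k] > 0:
                naive -= q_t[j, k] * np.log(trans.p_round_t[j, k]) / n
    assert loss == pytest.approx(naive, abs=1e-10)


def test_supervised_objective_cases(rng):
    logits = rng.normal(size=(3, 2))
    assert ca.supervised_objective(np.zeros((3, 2)), logits) == 0.0
    # strongly favored correct class -> loss ~ 0
    A = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
    big = np.array([[50.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
    assert ca.supervised_objective(A, big) < 1e-10
    # hand-computed softmax CE over the labeled rows
    A = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    expected = 0.0
    for i in range(2):
        p = np.exp(logits[i]) / np.exp(logits[i]).sum()
        expected -= np.log(p[np.argmax(A[i])])
    assert ca.supervised_objective(A, logits) == pytest.approx(expected / 2, abs=1e-12)


def test_total_objective_reduces_to_walker(rng):
    cfg = _config(ridge=0.0, batch_norm=False)
    model = ca.build_encoder(5, cfg)
    X = {"a": rng.normal(size=(4, 5)), "b": rng.normal(size=(3, 5))}
    total, parts = ca.total_objective(model, X)
    assert parts["supervised"] == 0.0
    assert total == pytest.approx(parts["walker"], abs=1e-12)
    # cross-check walker against the numpy objective on the same embeddings
    E = {c: ca.embed_cells(model, X[c]) for c in X}
    trans = ca.embedding_transitions(E["a"], E["b"])
    kerns = {c: ca.expression_transition_matrix(X[c], perplexity=cfg.perplexity)
             for c in X}
    loss, _ = ca.walker_objective(kerns["a"], kerns["b"], trans)
    assert parts["walker"] == pytest.approx(loss, abs=1e-10)


def test_zero_weight_ridge_is_zero(rng):
    model = ca.build_encoder(4, _config(ridge=1.0, batch_norm=False))
    for W in model.encoder.weight_matrices():
        W.data[:] = 0.0
    X = {"a": rng.normal(size=(3, 4)), "b": rng.normal(size=(3, 4))}
    _, parts = ca.total_objective(model, X)
    assert parts["ridge"] == 0.0


def test_gradient_matches_finite_differences(rng):
    """Backprop through encoder, batch-norm, walker + supervised + ridge."""
    cfg = _config(hidden_sizes=(4,), ridge=1e-3)
    model = ca.build_encoder(5, cfg)
    model.head = Linear(2, 2, np.random.default_rng(1))
    X = {"a": rng.normal(size=(3, 5)), "b": rng.normal(size=(3, 5))}
    A = {"a": np.array([[1, 0], [0, 1], [0, 0]], float),
         "b": np.array([[0, 1], [0, 0], [1, 0]], float)}
    loss0, grad, params = objective_gradient(model, X, A)
    flat = np.concatenate([p.data.ravel() for p in params])

    def set_flat(v):
        pos = 0
        for p in params:
            p.data = v[pos:pos + p.data.size].reshape(p.data.shape).copy()
            pos += p.data.size

    eps = 1e-6
    num = np.zeros_like(flat)
    for i in range(flat.size):
        v = flat.copy(); v[i] += eps; set_flat(v)
        lp, _ = ca.total_objective(model, X, A)
        v[i] -= 2 * eps; set_flat(v)
        lm, _ = ca.total_objective(model, X, A)
        num[i] = (lp - lm) / (2 * eps)
    set_flat(flat)
    rel = np.abs(num - grad) / np.maximum(1e-8, np.abs(num) + np.abs(grad))
    assert rel.max() < 1e-4


def test_walker_rotation_invariance(rng):
    """Joint orthogonal rotation of all embeddings leaves the loss unchanged."""
    E_s, E_t = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
    R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    q_s = ca.expression_transition_matrix(rng.normal(size=(5, 2)), perplexity=3)
    q_t = ca.expression_transition_matrix(rng.normal(size=(4, 2)), perplexity=3)
    l1, _ = ca.walker_objective(q_s, q_t, ca.embedding_transitions(E_s, E_t))
    l2, _ = ca.walker_objective(q_s, q_t, ca.embedding_transitions(E_s @ R, E_t @ R))
    assert l1 == pytest.approx(l2, abs=1e-9)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _twin_dataset(rng, n=40, g=12):
    base = rng.normal(size=(n, g))
    values = np.vstack([base, base])
    return ca.ExpressionDataset(
        values=values,
        cell_ids=[f"c{i}" for i in range(2 * n)],
        feature_ids=[f"g{j}" for j in range(g)],
        condition_of=np.array(["a"] * n + ["b"] * n, dtype=object),
        layer="log",
    )


def test_training_identical_conditions_concentrates_on_twins(rng):
    ds = _twin_dataset(rng)
    n = 40
    cfg = _config(hidden_sizes=(16,), embedding_dim=4, max_steps=400,
                  learning_rate=2e-3, batch_size=n, perplexity=10)
    model = ca.train_alignment(ds, None, cfg)
    E = ca.embed_cells(model, ds)
    trans = ca.embedding_transitions(E[:n], E[n:])
    twin_mass = np.mean([trans.p_fwd[i, i] for i in range(n)])
    assert twin_mass > 10 / n


def test_pairwise_mode_rejects_three_conditions(rng):
    values = rng.poisson(3.0, size=(9, 5)).astype(float)
    ds = ca.ExpressionDataset(
        values=values, cell_ids=[f"c{i}" for i in range(9)],
        feature_ids=[f"g{j}" for j in range(5)],
        condition_of=np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3, dtype=object),
    )
    with pytest.raises(ValueError, match="pairwise"):
        ca.train_alignment(ds, None, _config(mode="pairwise", max_steps=1))


def test_training_seed_determinism(rng):
    ds = _twin_dataset(rng, n=15, g=6)
    cfg = _config(hidden_sizes=(8,), embedding_dim=3, max_steps=20,
                  batch_size=20, perplexity=5)
    with pytest.warns(UserWarning):  # batch == condition size
        m1 = ca.train_alignment(ds, None, cfg)
        m2 = ca.train_alignment(ds, None, cfg)
    t1 = [r["total"] for r in m1.loss_trace]
    t2 = [r["total"] for r in m2.loss_trace]
    np.testing.assert_array_equal(t1, t2)


def test_row_stochastic_during_training(small_model):
    model, proc, _ = small_model
    E = {c: ca.embed_cells(model, proc.subset_cells(proc.condition_mask(c)))
         for c in proc.conditions}
    conds = proc.conditions
    trans = ca.embedding_transitions(E[conds[0]], E[conds[1]])
    for M in (trans.p_fwd, trans.p_bwd, trans.p_round_s, trans.p_round_t):
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(M >= 0)


def test_embed_cells_deterministic_and_duplicates(small_model, rng):
    model, proc, _ = small_model
    X = proc.values[:5]
    X2 = np.vstack([X, X[:1]])
    E = ca.embed_cells(model, X2)
    np.testing.assert_array_equal(E[0], E[5])
    np.testing.assert_array_equal(E, ca.embed_cells(model, X2))
    with pytest.raises(ValueError, match="features"):
        ca.embed_cells(model, rng.normal(size=(3, proc.n_features + 1)))


def test_checkpoint_roundtrip(tmp_path, small_model):
    model, proc, _ = small_model
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = ca.AlignmentModel.load(path)
    np.testing.assert_array_equal(
        ca.embed_cells(model, proc), ca.embed_cells(loaded, proc)
    )
    assert loaded.config == model.config


# ---------------------------------------------------------------------------
# shared autoencoder baseline
# ---------------------------------------------------------------------------

def test_autoencoder_learns_identity_on_low_rank(rng):
    # rank-2 data, linear encoder/decoder with K = 2: MSE must approach 0
    n, g, k = 30, 6, 2
    base = rng.normal(size=(n, k)) @ rng.normal(size=(k, g))
    ds = ca.ExpressionDataset(
        values=np.vstack([base, base + 0.0]),
        cell_ids=[f"c{i}" for i in range(2 * n)],
        feature_ids=[f"g{j}" for j in range(g)],
        condition_of=np.array(["a"] * n + ["b"] * n, dtype=object),
        layer="log",
    )
    cfg = _config(hidden_sizes=(), embedding_dim=k, batch_norm=False,
                  ridge=0.0, max_steps=2000, learning_rate=1e-2, batch_size=n)
    model, decoders = ca.train_shared_autoencoder(ds, cfg)
    E = ca.embed_cells(model, ds)
    mse = np.mean((decoders["a"](E[:n], training=False).data - base) ** 2)
    assert mse < 1e-3
    # untrained model reconstruction error is on the variance scale of the data
    cfg0 = _config(hidden_sizes=(), embedding_dim=k, batch_norm=False,
                   ridge=0.0, max_steps=1, learning_rate=1e-9, batch_size=n)
    m0, _ = ca.train_shared_autoencoder(ds, cfg0)
    assert m0.loss_trace[0]["reconstruction"] > 0.1 * base.var()


def test_autoencoder_seed_determinism(rng):
    ds = _twin_dataset(rng, n=12, g=5)
    cfg = _config(hidden_sizes=(6,), embedding_dim=2, max_steps=15,
                  batch_size=16, perplexity=5)
    with pytest.warns(UserWarning):
        a, _ = ca.train_shared_autoencoder(ds, cfg)
        b, _ = ca.train_shared_autoencoder(ds, cfg)
    np.testing.assert_array_equal(
        [r["total"] for r in a.loss_trace], [r["total"] for r in b.loss_trace]
    )
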