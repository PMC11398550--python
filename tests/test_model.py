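"""Layer-by-layer checks of the network against independent loop oracles."""

import numpy as np
import pytest

import legnet
from legnet.model import (PHI, calibrated_init, expected_shapes, forward_batch,
                          loss_and_grads, softmax)
from legnet.errors import ContractError

from conftest import random_instance

HP_SMALL = legnet.HyperParams(k=3, d0=2, d1=3, d2=2, d3=3, lam=0.01)


# ---------------------------------------------------------------------------
# independent nested-loop reference implementations


def oracle_edge_to_edge(X, params, hp):
    n = X.shape[0]
    phi = PHI[hp.phi][0]
    H = np.zeros((n, n, hp.d0))
    for i in range(n):
        for j in range(n):
            acc = np.zeros(hp.d0)
            for m in range(n):
                acc += params.r[m] * X[i, m] + params.c[m] * X[m, j]
            H[i, j] = phi(acc)
    return H


def oracle_edge_to_node(H, params, hp):
    n = H.shape[0]
    phi = PHI[hp.phi][0]
    h = np.zeros((n, hp.d1))
    for i in range(n):
        acc = params.b1.copy()
        for m in range(n):
            acc = acc + params.g[m] @ H[i, m]
        h[i] = phi(acc)
    return h


def oracle_scores(theta1, p, hp):
    n = len(p)
    S = np.zeros((n, hp.k))
    for j in range(n):
        logits = p[j] * theta1[:, j]
        if hp.psi == "softmax":
            e = np.exp(logits - logits.max())
            S[j] = e / e.sum()
        else:
            S[j] = 1 / (1 + np.exp(-logits))
    return S


def oracle_filters(theta2, S, b2, hp):
    n = S.shape[0]
    W = np.zeros((n, hp.d2, hp.d1))
    for j in range(n):
        vec = theta2 @ S[j] + b2
        for col in range(hp.d1):          # column-major unstacking
            for row in range(hp.d2):
                W[j, row, col] = vec[col * hp.d2 + row]
    return W


def oracle_update(h1, W, hp):
    n = h1.shape[0]
    phi = PHI[hp.phi][0]
    z = np.zeros(hp.d2)
    for j in range(n):
        z = z + W[j] @ h1[j]
    return np.tile(phi(z), (n, 1))


def oracle_readout(h2, params, hp):
    phi = PHI[hp.phi][0]
    u = phi(params.W3 @ h2.reshape(-1) + params.b3)
    return float(params.w_out @ u + params.b_out)


def oracle_forward(X, p, params, hp):
    H = oracle_edge_to_edge(X, params, hp)
    h1 = oracle_edge_to_node(H, params, hp)
    S = oracle_scores(params.theta1, p, hp)
    W = oracle_filters(params.theta2, S, params.b2, hp)
    h2 = oracle_update(h1, W, hp)
    return oracle_readout(h2, params, hp), S


# ---------------------------------------------------------------------------
# oracle equivalence


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("n", [2, 4, 6])
def test_layers_match_loop_oracles(n, seed):
    """Each vectorized layer reproduces the nested-loop reference elementwise."""
    X, p, params = random_instance(n, HP_SMALL, seed)
    H = legnet.edge_to_edge(X, params, HP_SMALL)
    assert np.allclose(H, oracle_edge_to_edge(X, params, HP_SMALL), atol=1e-6)
    h1 = legnet.edge_to_node(H, params, HP_SMALL)
    assert np.allclose(h1, oracle_edge_to_node(H, params, HP_SMALL), atol=1e-6)
    L = legnet.lesion_embedding(p)
    S = legnet.subgraph_scores(params.theta1, L, HP_SMALL.psi)
    assert np.allclose(S, oracle_scores(params.theta1, p, HP_SMALL), atol=1e-9)
    W = legnet.node_filters(params.theta2, S, params.b2, HP_SMALL)
    assert np.allclose(W, oracle_filters(params.theta2, S, params.b2, HP_SMALL), atol=1e-9)
    h2 = legnet.subgraph_update(h1, W, HP_SMALL)
    assert np.allclose(h2, oracle_update(h1, W, HP_SMALL), atol=1e-6)
    yhat = legnet.readout(h2, params, HP_SMALL)
    assert yhat == pytest.approx(oracle_readout(h2, params, HP_SMALL), abs=1e-6)


@pytest.mark.parametrize("seed", range(8))
def test_forward_matches_composed_oracles(seed):
    """The end-to-end forward pass equals the composition of the loop oracles."""
    X, p, params = random_instance(5, HP_SMALL, seed + 100)
    yhat, S = legnet.forward(X, p, params, HP_SMALL)
    y_ref, S_ref = oracle_forward(X, p, params, HP_SMALL)
    assert yhat == pytest.approx(y_ref, abs=1e-6)
    assert np.allclose(S, S_ref, atol=1e-9)


def test_batched_forward_matches_single():
    rng = np.random.default_rng(3)
    Xs, ps = [], []
    for s in range(4):
        X, p, _ = random_instance(5, HP_SMALL, s)
        Xs.append(X)
        ps.append(p)
    _, _, params = random_instance(5, HP_SMALL, 42)
    yb, Sb = forward_batch(np.stack(Xs), np.stack(ps), params, HP_SMALL)
    for m in range(4):
        y1, S1 = legnet.forward(Xs[m], ps[m], params, HP_SMALL)
        assert yb[m] == pytest.approx(y1, abs=1e-9)
        assert np.allclose(Sb[m], S1, atol=1e-12)


# ---------------------------------------------------------------------------
# closed-form special cases


def test_zero_params_give_zero_prediction_uniform_scores():
    hp = HP_SMALL
    X, p, params = random_instance(4, hp, 0)
    zero = legnet.init_params(4, hp, seed=0, scale=0.0, bias_shift=0.0)
    yhat, S = legnet.forward(X, p, zero, hp)
    assert yhat == 0.0
    assert np.allclose(S, 1.0 / hp.k)


def test_single_node_closed_form():
    hp = legnet.HyperParams(k=1, d0=1, d1=1, d2=1, d3=1, phi="relu")
    params = legnet.init_params(1, hp, seed=0)
    x = 1.7
    H = legnet.edge_to_edge(np.array([[x]]), params, hp)
    expected = max((params.r[0, 0] + params.c[0, 0]) * x, 0.0)
    assert H[0, 0, 0] == pytest.approx(expected)


def test_lesion_embedding_diagonal():
    L = legnet.lesion_embedding(np.array([1.0, 0.5]))
    assert np.allclose(L, np.diag([1.0, 0.5]))
    with pytest.raises(ContractError):
        legnet.lesion_embedding(np.array([1.2]))


def test_assignment_rows_sum_to_one():
    _, p, params = random_instance(6, HP_SMALL, 9)
    S = legnet.subgraph_scores(params.theta1, np.diag(p))
    assert np.allclose(S.sum(axis=1), 1.0, atol=1e-9)


def test_one_hot_scores_select_theta2_column():
    hp = HP_SMALL
    S = np.zeros((3, hp.k))
    S[:, 1] = 1.0
    theta2 = np.random.default_rng(0).standard_normal((hp.d2 * hp.d1, hp.k))
    W = legnet.node_filters(theta2, S, np.zeros(hp.d2 * hp.d1), hp)
    col = theta2[:, 1]
    expect = np.zeros((hp.d2, hp.d1))
    for c in range(hp.d1):
        for r in range(hp.d2):
            expect[r, c] = col[c * hp.d2 + r]
    assert np.allclose(W[0], expect)


def test_readout_constant_when_head_zeroed():
    X, p, params = random_instance(4, HP_SMALL, 2)
    params.w_out[:] = 0.0
    params.b_out = np.asarray(42.0)
    yhat, _ = legnet.forward(X, p, params, HP_SMALL)
    assert yhat == pytest.approx(42.0)


# ---------------------------------------------------------------------------
# structural properties


def test_parameter_count_matches_shape_enumeration():
    n, hp = 7, HP_SMALL
    params = legnet.init_params(n, hp, seed=0)
    expect = sum(int(np.prod(s)) if s else 1
                 for s in expected_shapes(n, hp).values())
    assert params.n_parameters() == expect


def test_forward_is_deterministic():
    X, p, params = random_instance(5, HP_SMALL, 7)
    y1, S1 = legnet.forward(X, p, params, HP_SMALL)
    y2, S2 = legnet.forward(X, p, params, HP_SMALL)
    assert y1 == y2 and np.array_equal(S1, S2)


def test_prediction_invariant_under_node_permutation():
    """Relabeling ROIs together with all per-node parameters leaves yhat unchanged."""
    n = 5
    X, p, params = random_instance(n, HP_SMALL, 13)
    perm = np.random.default_rng(0).permutation(n)
    Xp = X[np.ix_(perm, perm)]
    pp = p[perm]
    q = params.copy()
    q.r, q.c, q.g = params.r[perm], params.c[perm], params.g[perm]
    q.theta1 = params.theta1[:, perm]
    # W3 columns follow flatten(h2); h2 rows are identical so blocks may permute
    q.W3 = params.W3.reshape(HP_SMALL.d3, n, HP_SMALL.d2)[:, perm].reshape(HP_SMALL.d3, -1)
    y0, _ = legnet.forward(X, p, params, HP_SMALL)
    y1, _ = legnet.forward(Xp, pp, q, HP_SMALL)
    assert y1 == pytest.approx(y0, rel=1e-9)


# ---------------------------------------------------------------------------
# loss and gradients


def test_loss_closed_forms():
    params = legnet.init_params(3, HP_SMALL, seed=0, scale=0.0)
    hp0 = legnet.HyperParams(k=3, d0=2, d1=3, d2=2, d3=3, lam=0.0)
    assert legnet.loss([1.0, 2.0], [1.0, 2.0], params, hp0) == 0.0
    assert legnet.loss([1.0, 2.0], [0.0, 0.0], params, hp0) == pytest.approx(2.5)
    with pytest.raises(ContractError):
        legnet.loss([], [], params, hp0)


def test_regularizer_covers_exactly_the_network_filters():
    params = legnet.init_params(3, HP_SMALL, seed=1)
    hp = legnet.HyperParams(k=3, d0=2, d1=3, d2=2, d3=3, lam=0.5)
    base = legnet.loss([0.0], [0.0], params, hp)
    # readout weights are excluded: changing them (with zero prediction path
    # impossible) — instead verify via the penalty itself
    expect = sum(np.sum(getattr(params, n) ** 2)
                 for n in ("theta1", "theta2", "b1", "b2", "r", "c", "g"))
    assert base == pytest.approx(0.5 * expect)
    params.W3 += 1.0
    assert legnet.loss([0.0], [0.0], params, hp) == pytest.approx(0.5 * expect)


@pytest.mark.parametrize("phi", ["leaky_relu", "relu", "tanh"])
def test_gradients_match_finite_differences(phi):
    """Hand-derived backprop agrees with central finite differences."""
    hp = legnet.HyperParams(k=3, d0=2, d1=3, d2=2, d3=3, lam=0.01, phi=phi)
    rng = np.random.default_rng(5)
    M, n = 3, 5
    X = rng.uniform(np.exp(-1), np.exp(1), (M, n, n))
    X = (X + X.swapaxes(1, 2)) / 2
    p = rng.uniform(0, 1, (M, n))
    y = rng.normal(0, 1, M)
    params = legnet.init_params(n, hp, seed=2)
    _, grads = loss_and_grads(X, p, y, params, hp)
    eps = 1e-6
    rng2 = np.random.default_rng(0)
    for name, arr in params.arrays().items():
        flat = arr.reshape(-1) if arr.ndim else None
        idxs = (rng2.choice(arr.size, size=min(6, arr.size), replace=False)
                if arr.ndim else [None])
        for ix in idxs:
            ref = flat if arr.ndim else None
            if arr.ndim:
                orig = flat[ix]
                flat[ix] = orig + eps
                lp, _ = loss_and_grads(X, p, y, params, hp)
                flat[ix] = orig - eps
                lm, _ = loss_and_grads(X, p, y, params, hp)
                flat[ix] = orig
                ana = getattr(grads, name).reshape(-1)[ix]
            else:
                orig = arr.item()
                setattr(params, name, np.asarray(orig + eps))
                lp, _ = loss_and_grads(X, p, y, params, hp)
                setattr(params, name, np.asarray(orig - eps))
                lm, _ = loss_and_grads(X, p, y, params, hp)
                setattr(params, name, np.asarray(orig))
                ana = float(getattr(grads, name))
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(ana), 1e-8)
            assert abs(fd - ana) / denom < 1e-4, f"{name}[{ix}]: fd={fd} ana={ana}"


def test_checkpoint_roundtrip(tmp_path):
    params = legnet.init_params(4, HP_SMALL, seed=3)
    path = tmp_path / "ckpt.json"
    legnet.save_checkpoint(path, params, HP_SMALL, metadata={"note": 1})
    loaded, hp, meta = legnet.load_checkpoint(path)
    assert hp == HP_SMALL and meta["note"] == 1
    for name, arr in params.arrays().items():
        assert np.allclose(arr, getattr(loaded, name), atol=0)


def test_calibrated_init_starts_healthy():
    """Calibrated init yields O(1), non-constant predictions at epoch 0."""
    rng = np.random.default_rng(8)
    M, n = 20, 10
    X = rng.normal(0, 1, (M, n, n))
    X = (X + X.swapaxes(1, 2)) / 2
    p = rng.uniform(0.5, 1, (M, n))
    hp = legnet.HyperParams(k=4, d0=3, d1=4, d2=2, d3=4)
    params = calibrated_init(X, p, hp, seed=0)
    yhat, _ = forward_batch(X, p, params, hp)
    assert np.std(yhat) > 0.05
    assert np.abs(yhat).max() < 10
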