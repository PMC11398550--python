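"""LEGNet: lesion-aware edge-based graph network for connectome regression.

The network predicts a scalar behavioral score (0–100, WAB-AQ-like) from an
N × N functional-connectivity matrix X and a per-ROI spared-gray-matter vector
p.  It has three stages:

1. *Edge-based learning.*  An edge-to-edge convolution updates each edge
   feature from all edges sharing one of its end-nodes,

       H_ij = phi( sum_n r_n X_in  +  sum_n c_n X_nj ),        (N × N × d0)

   with per-node row/column filters r_n, c_n in R^d0, followed by an
   edge-to-node aggregation

       h_i = phi( sum_n g_n H_in + b1 ),                        (N × d1)

   with per-node filter matrices g_n in R^{d1 x d0}.  The neighborhood is the
   full node set (the correlation connectome is dense), including the node
   itself.

2. *Lesion encoding.*  L = diag(p) embeds lesion size and position; the j-th
   column L_j = p_j e_j carries ROI j's sparing.

3. *Subgraph learning.*  Each node receives an assignment score over k
   subgraphs, S_j = psi(Theta1 L_j) (psi = softmax by default, so rows sum
   to 1), and a node-specific filter generated from it,

       vec(W_j) = Theta2 S_j + b2   (column-major vec, W_j in R^{d2 x d1})
       h'_i = phi( sum_j W_j h_j ),                             (N × d2)

   so ROIs with similar lesion encodings are updated by similar filters.  The
   flattened node features pass through one hidden fully connected layer of
   width d3 to the scalar prediction.

Training minimizes mean squared error plus an L2 (ridge) penalty on the
network filters Theta1, Theta2, b1, b2, r, c, g (the readout head is not
penalized).

Everything is plain NumPy; gradients are derived by hand and verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

from .errors import ContractError

# ---------------------------------------------------------------------------
# activations


def _relu(x):
    return np.maximum(x, 0.0)


def _drelu(x):
    return (x > 0).astype(float)


def _tanh(x):
    return np.tanh(x)


def _dtanh(x):
    return 1.0 - np.tanh(x) ** 2


def _identity(x):
    return x


def _didentity(x):
    return np.ones_like(x)


_LEAKY_SLOPE = 0.01


def _leaky_relu(x):
    return np.where(x > 0, x, _LEAKY_SLOPE * x)


def _dleaky_relu(x):
    return np.where(x > 0, 1.0, _LEAKY_SLOPE)


PHI = {
    "relu": (_relu, _drelu),
    "leaky_relu": (_leaky_relu, _dleaky_relu),
    "tanh": (_tanh, _dtanh),
    "identity": (_identity, _didentity),
}


def softmax(a, axis=-1):
    a = a - a.max(axis=axis, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# hyperparameters and parameters


@dataclass(frozen=True)
class HyperParams:
    """Architecture hyperparameters.

    Defaults are the grid-search selection reported for the method:
    lambda = 0.005, k = 8, d0 = 4, d1 = 8, d2 = 2, d3 = 8.
    """

    k: int = 8
    d0: int = 4
    d1: int = 8
    d2: int = 2
    d3: int = 8
    lam: float = 0.005
    phi: str = "leaky_relu"  # plain relu can die permanently at the d2 bottleneck
    psi: str = "softmax"

    def __post_init__(self):
        if min(self.k, self.d0, self.d1, self.d2, self.d3) < 1:
            raise ContractError("all widths and k must be >= 1")
        if self.lam < 0:
            raise ContractError("lambda must be >= 0")
        if self.phi not in PHI:
            raise ContractError(f"unknown activation {self.phi!r}")
        if self.psi not in ("softmax", "sigmoid"):
            raise ContractError(f"unknown assignment activation {self.psi!r}")

    def to_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class LEGNetParams:
    """All learnable tensors for a given (N, HyperParams)."""

    r: np.ndarray       # N x d0 row filters
    c: np.ndarray       # N x d0 column filters
    g: np.ndarray       # N x d1 x d0 edge-to-node filters
    b1: np.ndarray      # d1
    theta1: np.ndarray  # k x N subgraph assignment weights
    theta2: np.ndarray  # (d2*d1) x k filter generator
    b2: np.ndarray      # d2*d1
    W3: np.ndarray      # d3 x (N*d2) readout hidden weights
    b3: np.ndarray      # d3
    w_out: np.ndarray   # d3
    b_out: np.ndarray   # scalar (shape ())

    REGULARIZED = ("theta1", "theta2", "b1", "b2", "r", "c", "g")

    def arrays(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def copy(self) -> "LEGNetParams":
        return LEGNetParams(**{k: v.copy() for k, v in self.arrays().items()})

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.arrays().values()))

    def l2_penalty(self) -> float:
        return float(sum(np.sum(getattr(self, name) ** 2) for name in self.REGULARIZED))

    def validate_shapes(self, n_rois: int, hp: HyperParams) -> None:
        expect = expected_shapes(n_rois, hp)
        for name, shape in expect.items():
            got = getattr(self, name).shape
            if tuple(got) != shape:
                raise ContractError(f"parameter {name}: shape {got}, expected {shape}")


def expected_shapes(n_rois: int, hp: HyperParams) -> dict:
    N = n_rois
    return {
        "r": (N, hp.d0), "c": (N, hp.d0), "g": (N, hp.d1, hp.d0), "b1": (hp.d1,),
        "theta1": (hp.k, N), "theta2": (hp.d2 * hp.d1, hp.k), "b2": (hp.d2 * hp.d1,),
        "W3": (hp.d3, N * hp.d2), "b3": (hp.d3,), "w_out": (hp.d3,), "b_out": (),
    }


def init_params(n_rois: int, hp: HyperParams, seed: int = 0,
                scale: float = 1.0, bias_shift: float = 0.1) -> LEGNetParams:
    """Fan-in-scaled symmetric random initialization.

    Each weight tensor is drawn with standard deviation scale/sqrt(fan_in),
    where fan_in is the number of summed terms feeding one output coordinate
    (N for the edge filters, N*d0 for the edge-to-node filters, and so on),
    so pre-activations start O(1) regardless of N and the layer widths.
    Biases start at a small positive ``bias_shift`` because the subgraph
    update has no centering term: with zero biases its ReLU inputs can start
    dead for every subject at once.
    """
    rng = np.random.default_rng(seed)
    N = n_rois
    fan_in = {
        "r": N, "c": N, "g": N * hp.d0, "theta1": 1, "theta2": hp.k,
        "W3": N * hp.d2, "w_out": hp.d3,
    }
    shapes = expected_shapes(n_rois, hp)
    vals = {}
    for name, shape in shapes.items():
        if name == "b_out":
            vals[name] = np.zeros(shape)
        elif name in ("b1", "b2", "b3"):
            vals[name] = np.full(shape, bias_shift)
        else:
            vals[name] = (scale / np.sqrt(fan_in[name])) * rng.standard_normal(shape)
    return LEGNetParams(**vals)


def zeros_like_params(params: LEGNetParams) -> LEGNetParams:
    return LEGNetParams(**{k: np.zeros_like(v) for k, v in params.arrays().items()})


# ---------------------------------------------------------------------------
# layer operations (single-subject surface; batched kernels underneath)


def _as_batch(X, p):
    X = np.asarray(X, dtype=float)
    p = np.asarray(p, dtype=float)
    single = X.ndim == 2
    if single:
        X, p = X[None], p[None]
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ContractError(f"X must be (..., N, N); got {X.shape}")
    if p.shape != X.shape[:2]:
        raise ContractError(f"p shape {p.shape} inconsistent with X {X.shape}")
    return X, p, single


def edge_to_edge(X: np.ndarray, params: LEGNetParams, hp: HyperParams) -> np.ndarray:
    """Edge feature map H (N × N × d0): H_ij = phi(sum_n r_n X_in + sum_n c_n X_nj)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1] or X.shape[0] != params.r.shape[0]:
        raise ContractError(f"X shape {X.shape} inconsistent with params N={params.r.shape[0]}")
    phi, _ = PHI[hp.phi]
    A = X @ params.r           # A[i] = sum_n X_in r_n
    B = X.T @ params.c         # B[j] = sum_n X_nj c_n
    return phi(A[:, None, :] + B[None, :, :])


def edge_to_node(H: np.ndarray, params: LEGNetParams, hp: HyperParams) -> np.ndarray:
    """Node features h (N × d1): h_i = phi(sum_n g_n H_in + b1)."""
    H = np.asarray(H, dtype=float)
    N = params.g.shape[0]
    if H.shape != (N, N, hp.d0):
        raise ContractError(f"H shape {H.shape}, expected {(N, N, hp.d0)}")
    phi, _ = PHI[hp.phi]
    return phi(np.einsum("nef,inf->ie", params.g, H) + params.b1)


def lesion_embedding(p: np.ndarray) -> np.ndarray:
    """Diagonal lesion embedding L = diag(p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ContractError("spared fractions must lie in [0, 1]")
    return np.diag(p)


def _psi_scores(logits: np.ndarray, psi: str) -> np.ndarray:
    if psi == "softmax":
        return softmax(logits, axis=-1)
    return 1.0 / (1.0 + np.exp(-logits))


def subgraph_scores(theta1: np.ndarray, L: np.ndarray, psi: str = "softmax") -> np.ndarray:
    """N × k assignment scores; row j = psi(Theta1 L_j).

    With psi = softmax each row sums to 1 and reads as node j's involvement
    in each of the k subgraphs.
    """
    logits = (theta1 @ L).T  # row j = Theta1 L_j
    return _psi_scores(logits, psi)


def node_filters(theta2: np.ndarray, S: np.ndarray, b2: np.ndarray,
                 hp: HyperParams) -> np.ndarray:
    """Per-node filters W_j (N × d2 × d1) with vec(W_j) = Theta2 S_j + b2.

    vec is column-major: entry v of the vector maps to (v mod d2, v div d2).
    """
    if S.shape[1] != theta2.shape[1]:
        raise ContractError("S and Theta2 disagree on k")
    vec = S @ theta2.T + b2  # N x (d2*d1)
    return vec.reshape(S.shape[0], hp.d1, hp.d2).swapaxes(-1, -2)


def subgraph_update(h1: np.ndarray, W: np.ndarray, hp: HyperParams) -> np.ndarray:
    """h'_i = phi(sum_j W_j h_j): lesion-conditioned node update (N × d2).

    With the full-neighborhood convention the inner sum does not depend on i,
    so all rows are equal; per-node variation enters through W_j and S.
    """
    if h1.shape != (W.shape[0], hp.d1):
        raise ContractError(f"h1 shape {h1.shape}, expected {(W.shape[0], hp.d1)}")
    phi, _ = PHI[hp.phi]
    z = np.einsum("jab,jb->a", W, h1)
    return np.tile(phi(z), (h1.shape[0], 1))


def readout(h2: np.ndarray, params: LEGNetParams, hp: HyperParams) -> float:
    """Scalar prediction from flattened node features via one hidden layer."""
    N = params.r.shape[0]
    if h2.shape != (N, hp.d2):
        raise ContractError(f"h2 shape {h2.shape}, expected {(N, hp.d2)}")
    phi, _ = PHI[hp.phi]
    u = phi(params.W3 @ h2.reshape(-1) + params.b3)
    return float(params.w_out @ u + params.b_out)


# ---------------------------------------------------------------------------
# batched forward / backward


def forward_batch(X: np.ndarray, p: np.ndarray, params: LEGNetParams,
                  hp: HyperParams, want_cache: bool = False):
    """Vectorized forward pass over a batch.

    Returns (yhat (M,), S (M, N, k)) and, if requested, the cache of
    intermediates needed for backprop.
    """
    X, p, single = _as_batch(X, p)
    N = X.shape[1]
    M = X.shape[0]
    params.validate_shapes(N, hp)
    if np.any(p < 0) or np.any(p > 1):
        raise ContractError("spared fractions must lie in [0, 1]")
    phi, _ = PHI[hp.phi]

    A = X @ params.r                         # (M, N, d0)
    B = X.transpose(0, 2, 1) @ params.c      # (M, N, d0)
    Hpre = A[:, :, None, :] + B[:, None, :, :]
    H = phi(Hpre)

    # h1pre[m,i] = sum_{n,f} g[n,:,f] H[m,i,n,f] + b1 — one GEMM
    g_mat = params.g.transpose(0, 2, 1).reshape(N * hp.d0, hp.d1)
    h1pre = (H.reshape(M * N, N * hp.d0) @ g_mat).reshape(M, N, hp.d1) + params.b1
    h1 = phi(h1pre)

    logits = p[:, :, None] * params.theta1.T[None, :, :]  # (M, N, k)
    S = _psi_scores(logits, hp.psi)

    vec = np.einsum("vk,mjk->mjv", params.theta2, S) + params.b2
    W = vec.reshape(X.shape[0], N, hp.d1, hp.d2).swapaxes(-1, -2)  # column-major vec

    z = np.einsum("mjab,mjb->ma", W, h1)
    phi_z = phi(z)                      # (M, d2); h2 rows all equal phi(z)
    f = np.tile(phi_z, (1, N))          # row-major flatten of h2

    upre = f @ params.W3.T + params.b3
    u = phi(upre)
    yhat = u @ params.w_out + float(params.b_out)

    out_yhat = yhat[0] if single else yhat
    out_S = S[0] if single else S
    if not want_cache:
        return out_yhat, out_S
    cache = dict(X=X, p=p, A=A, B=B, Hpre=Hpre, H=H, h1pre=h1pre, h1=h1,
                 logits=logits, S=S, W=W, z=z, phi_z=phi_z, f=f, upre=upre,
                 u=u, yhat=yhat, single=single, N=N)
    return out_yhat, out_S, cache


def forward(X: np.ndarray, p: np.ndarray, params: LEGNetParams, hp: HyperParams):
    """Single-subject forward pass; returns (yhat, N × k assignment scores)."""
    return forward_batch(X, p, params, hp)


def loss(yhat, y, params: LEGNetParams, hp: HyperParams) -> float:
    """Mean squared error plus lambda times the ridge penalty on the filters."""
    yhat = np.atleast_1d(np.asarray(yhat, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if yhat.shape != y.shape or len(y) == 0:
        raise ContractError("prediction/target batches must be equal-length and nonempty")
    return float(np.mean((yhat - y) ** 2) + hp.lam * params.l2_penalty())


def loss_and_grads(X, p, y, params: LEGNetParams, hp: HyperParams):
    """Loss and its gradient with respect to every parameter.

    Backpropagation through the full architecture, batched over subjects.
    Returns (loss value, LEGNetParams of gradients).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    yhat, S, cache = forward_batch(X, p, params, hp, want_cache=True)
    yhat_b = cache["yhat"]
    M, N = yhat_b.shape[0], cache["N"]
    if y.shape != (M,):
        raise ContractError(f"targets shape {y.shape}, expected {(M,)}")
    _, dphi = PHI[hp.phi]

    value = float(np.mean((yhat_b - y) ** 2) + hp.lam * params.l2_penalty())
    dy = 2.0 * (yhat_b - y) / M  # (M,)

    g = zeros_like_params(params)
    # readout head
    g.b_out = np.asarray(dy.sum())
    g.w_out = cache["u"].T @ dy
    dupre = (dy[:, None] * params.w_out) * dphi(cache["upre"])  # (M, d3)
    g.W3 = dupre.T @ cache["f"]
    g.b3 = dupre.sum(axis=0)
    df = dupre @ params.W3                       # (M, N*d2)
    dphi_z = df.reshape(M, N, hp.d2).sum(axis=1)  # h2 rows share phi(z)
    dz = dphi_z * dphi(cache["z"])               # (M, d2)

    # subgraph update: z = sum_j W_j h1_j
    h1, W = cache["h1"], cache["W"]
    dW = np.einsum("ma,mjb->mjab", dz, h1)
    dh1 = np.einsum("mjab,ma->mjb", W, dz)

    # node filters: W_j = reshape(Theta2 S_j + b2), column-major
    dvec = dW.swapaxes(-1, -2).reshape(M, N, hp.d1 * hp.d2)
    g.theta2 = np.einsum("mjv,mjk->vk", dvec, cache["S"])
    g.b2 = dvec.sum(axis=(0, 1))
    dS = np.einsum("vk,mjv->mjk", params.theta2, dvec)

    # assignment scores: S = psi(p_j * theta1[:, j])
    if hp.psi == "softmax":
        Sc = cache["S"]
        dlogits = Sc * (dS - np.sum(dS * Sc, axis=-1, keepdims=True))
    else:  # sigmoid
        Sc = cache["S"]
        dlogits = dS * Sc * (1.0 - Sc)
    g.theta1 = np.einsum("mjk,mj->kj", dlogits, cache["p"])

    # edge-to-node: h1 = phi(einsum(g_n, H_in) + b1)
    dh1pre = dh1 * dphi(cache["h1pre"])  # (M, N, d1)
    Hflat = cache["H"].reshape(M * N, N * hp.d0)
    dg_mat = Hflat.T @ dh1pre.reshape(M * N, hp.d1)      # (N*d0, d1)
    g.g = dg_mat.reshape(N, hp.d0, hp.d1).transpose(0, 2, 1)
    g.b1 = dh1pre.sum(axis=(0, 1))
    g_mat = params.g.transpose(0, 2, 1).reshape(N * hp.d0, hp.d1)
    dH = (dh1pre.reshape(M * N, hp.d1) @ g_mat.T).reshape(M, N, N, hp.d0)

    # edge-to-edge: H = phi(A_i + B_j)
    dHpre = dH * dphi(cache["Hpre"])
    dA = dHpre.sum(axis=2)  # (M, N, d0)
    dB = dHpre.sum(axis=1)
    g.r = (cache["X"].transpose(0, 2, 1) @ dA).sum(axis=0)
    g.c = (cache["X"] @ dB).sum(axis=0)

    # ridge penalty on the filters named in the loss
    for name in LEGNetParams.REGULARIZED:
        setattr(g, name, getattr(g, name) + 2.0 * hp.lam * getattr(params, name))
    return value, g


def calibrated_init(X, p, hp: HyperParams, seed: int = 0,
                    scale: float = 1.0, target_spread: float = 0.5) -> LEGNetParams:
    """Data-calibrated initialization (layer-sequential unit-variance style).

    Starting from the fan-in-scaled random draw, each stage's weights are
    rescaled so its pre-activations have unit spread across the provided
    subjects, and the bias terms are set to center the pre-activations at a
    small positive value so every ReLU starts in its linear regime.  The
    edge-to-edge/edge-to-node sums run over all N nodes, so uncalibrated
    activation scales would otherwise grow with N and the layer widths,
    making the published learning rate unusable.

    Deterministic given (X, p, hp, seed).  X should be on the scale the model
    will be trained on (i.e. already standardized if the harness does so).
    """
    X, p, _ = _as_batch(X, p)
    params = init_params(X.shape[1], hp, seed=seed, scale=scale, bias_shift=0.0)
    phi, _ = PHI[hp.phi]
    eps = 1e-8

    def spread(a):  # pooled across-subject deviation
        return max(float(np.sqrt(np.mean((a - a.mean(axis=0)) ** 2))), eps)

    A = np.einsum("min,nf->mif", X, params.r)
    B = np.einsum("mnj,nf->mjf", X, params.c)
    s = spread(A[:, :, None, :] + B[:, None, :, :])
    params.r /= s
    params.c /= s
    H = phi((A[:, :, None, :] + B[:, None, :, :]) / s)

    h1pre = np.einsum("nef,minf->mie", params.g, H)
    s = spread(h1pre)
    params.g /= s
    h1pre /= s
    params.b1 = target_spread - h1pre.mean(axis=(0, 1))
    h1 = phi(h1pre + params.b1)

    logits = p[:, :, None] * params.theta1.T[None, :, :]
    S = _psi_scores(logits, hp.psi)
    vec = np.einsum("vk,mjk->mjv", params.theta2, S)
    W = vec.reshape(X.shape[0], X.shape[1], hp.d1, hp.d2).swapaxes(-1, -2)
    z = np.einsum("mjab,mjb->ma", W, h1)
    s = spread(z)
    params.theta2 /= s
    z /= s
    # b2 enters z through sum_j reshape(b2) h1_j; pick the rank-one b2 that
    # recenters the batch-mean of z at target_spread
    hbar = h1.sum(axis=1).mean(axis=0)  # (d1,)
    shift = target_spread - z.mean(axis=0)  # (d2,)
    B2 = np.outer(shift, hbar) / max(float(hbar @ hbar), eps)  # d2 x d1
    params.b2 = B2.T.reshape(-1)  # column-major vec
    z = z + (B2 @ h1.sum(axis=1).T).T
    phi_z = phi(z)
    f = np.tile(phi_z, (1, X.shape[1]))

    upre = f @ params.W3.T
    s = spread(upre)
    params.W3 /= s
    upre /= s
    params.b3 = target_spread - upre.mean(axis=0)
    u = phi(upre + params.b3)

    yraw = u @ params.w_out
    s = spread(yraw)
    params.w_out *= target_spread / s
    params.b_out = np.asarray(-(yraw * target_spread / s).mean())
    return params


# ---------------------------------------------------------------------------
# checkpoint serialization (portable JSON: shapes + flat value lists)


def save_checkpoint(path, params: LEGNetParams, hp: HyperParams,
                    metadata: Optional[dict] = None) -> None:
    blob = {
        "format": "legnet-checkpoint-v1",
        "hyperparams": hp.to_dict(),
        "metadata": metadata or {},
        "params": {
            name: {"shape": list(arr.shape), "values": np.asarray(arr, dtype=float).ravel().tolist()}
            for name, arr in params.arrays().items()
        },
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path):
    """Returns (params, hyperparams, metadata)."""
    with open(path) as fh:
        blob = json.load(fh)
    if blob.get("format") != "legnet-checkpoint-v1":
        raise ContractError(f"{path}: not a legnet checkpoint")
    hp = HyperParams(**blob["hyperparams"])
    arrays = {name: np.array(spec["values"], dtype=float).reshape(spec["shape"])
              for name, spec in blob["params"].items()}
    return LEGNetParams(**arrays), hp, blob.get("metadata", {})
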