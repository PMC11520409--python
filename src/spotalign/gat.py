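"""Graph-attention autoencoder over the spatial neighbor graph.

Encoder layer ``k`` aggregates linearly transformed neighbor features with
learned softmax attention:

    h_i^(k) = act( sum_{j in S_i} att_ij^(k) (W_k h_j^(k-1)) )

with attention logits

    e_ij^(k) = sigmoid( v_s^(k).(W_k h_i^(k-1)) + v_r^(k).(W_k h_j^(k-1)) )

normalized over each neighbor set by a softmax.  The decoder mirrors the
encoder with tied weights (W-hat_k = W_k^T) and the transposed attention
matrices, so the only free parameters are the encoder's W_k, v_s^(k),
v_r^(k).  The final encoder layer and the decoder output layer are linear, so
the latent space is unbounded and the reconstruction lives on the normalized
expression scale.

Everything here is plain NumPy: the network is small (two layers by default)
and trained full-batch, and the backward pass is derived analytically —
``backward`` returns exact gradients of any loss expressed through
``d loss / d reconstruction`` and ``d loss / d z`` (verified against finite
differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SpatialGraph

__all__ = [
    "GATParams",
    "Embedding",
    "init_params",
    "attention_weights",
    "encode",
    "decode",
    "autoencode",
    "forward",
    "backward",
    "reconstruction_loss",
    "save_params",
    "load_params",
]

_ACTIVATIONS = {
    "elu": (
        lambda x: np.where(x > 0, x, np.expm1(x)),
        lambda x: np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0))),
    ),
    "relu": (
        lambda x: np.maximum(x, 0.0),
        lambda x: (x > 0).astype(float),
    ),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class GATParams:
    """Tied-weight autoencoder parameters.

    ``layer_dims = [g, d_1, ..., d_K]``; ``W[k]`` has shape
    ``(d_{k+1}, d_k)``; the attention vectors ``v_s[k]``, ``v_r[k]`` have
    length ``d_{k+1}``.  The decoder stores nothing: it reuses ``W[k].T`` and
    the transposed encoder attention.
    """

    layer_dims: list[int]
    W: list[np.ndarray]
    v_s: list[np.ndarray]
    v_r: list[np.ndarray]
    activation: str = "elu"

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.W)
                   + sum(v.size for v in self.v_s)
                   + sum(v.size for v in self.v_r))

    def flat_list(self) -> list[np.ndarray]:
        return list(self.W) + list(self.v_s) + list(self.v_r)

    def copy(self) -> "GATParams":
        return GATParams(
            layer_dims=list(self.layer_dims),
            W=[w.copy() for w in self.W],
            v_s=[v.copy() for v in self.v_s],
            v_r=[v.copy() for v in self.v_r],
            activation=self.activation,
        )


@dataclass
class Embedding:
    """Latent spot embedding of one or more concatenated slices."""

    z: np.ndarray
    slice_ids: np.ndarray  # per-row source slice id

    def rows_of(self, slice_id) -> np.ndarray:
        return self.z[np.asarray(self.slice_ids) == slice_id]


def init_params(layer_dims: list[int], seed: int = 0,
                activation: str = "elu") -> GATParams:
    """Glorot-uniform initialization, deterministic in ``seed``."""
    if len(layer_dims) < 2:
        raise ValueError("need at least one layer")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    rng = np.random.RandomState(seed)
    W, v_s, v_r = [], [], []
    for d_in, d_out in zip(layer_dims[:-1], layer_dims[1:]):
        lim = np.sqrt(6.0 / (d_in + d_out))
        W.append(rng.uniform(-lim, lim, size=(d_out, d_in)))
        lim_v = np.sqrt(6.0 / (d_out + 1))
        v_s.append(rng.uniform(-lim_v, lim_v, size=d_out))
        v_r.append(rng.uniform(-lim_v, lim_v, size=d_out))
    return GATParams(layer_dims=list(layer_dims), W=W, v_s=v_s, v_r=v_r,
                     activation=activation)


def _masked_softmax(E: np.ndarray, mask: np.ndarray) -> np.ndarray:
    logits = np.where(mask, E, -np.inf)
    m = logits.max(axis=1, keepdims=True)
    expv = np.exp(logits - m)
    expv[~mask] = 0.0
    return expv / expv.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _layer_attention(P: np.ndarray, v_s: np.ndarray, v_r: np.ndarray,
                     mask: np.ndarray):
    """Attention matrix and its sigmoid pre-softmax values for one layer."""
    s = P @ v_s
    r = P @ v_r
    E = _sigmoid(s[:, None] + r[None, :])
    E = np.where(mask, E, 0.0)
    A = _masked_softmax(E, mask)
    return A, E


def attention_weights(h_prev: np.ndarray, graph: SpatialGraph, layer: int,
                      params: GATParams) -> np.ndarray:
    """Dense attention matrix ``att^(layer)`` (rows sum to 1 over S_i)."""
    mask = graph.mask_with_self()
    if h_prev.shape[0] != mask.shape[0]:
        raise ValueError("feature rows do not match graph size")
    P = h_prev @ params.W[layer].T
    A, _ = _layer_attention(P, params.v_s[layer], params.v_r[layer], mask)
    return A


def forward(H0: np.ndarray, graph: SpatialGraph, params: GATParams) -> dict:
    """Full autoencoder pass; returns a cache for ``backward``.

    Cache keys: ``H`` (encoder activations, H[0]=input, H[K]=z), ``P``,
    ``E``, ``A``, ``U`` per encoder layer; ``Q``, ``V``, ``Hhat`` per decoder
    layer (Hhat[0] is the reconstruction).
    """
    H0 = np.asarray(H0, dtype=float)
    mask = graph.mask_with_self()
    if H0.shape[0] != mask.shape[0]:
        raise ValueError("input rows do not match graph size")
    if H0.shape[1] != params.layer_dims[0]:
        raise ValueError(
            f"input has {H0.shape[1]} features but the first layer expects "
            f"{params.layer_dims[0]}")
    act, _ = _ACTIVATIONS[params.activation]
    K = params.n_layers

    H = [H0]
    P, E, A, U = [], [], [], []
    for k in range(K):
        Pk = H[k] @ params.W[k].T
        Ak, Ek = _layer_attention(Pk, params.v_s[k], params.v_r[k], mask)
        Uk = Ak @ Pk
        Hk1 = act(Uk) if k < K - 1 else Uk  # latent layer is linear
        P.append(Pk); E.append(Ek); A.append(Ak); U.append(Uk)
        H.append(Hk1)

    Hhat = [None] * (K + 1)
    Hhat[K] = H[K]
    Q = [None] * K
    V = [None] * K
    for k in range(K - 1, -1, -1):
        Qk = Hhat[k + 1] @ params.W[k]       # tied weights: W-hat_k = W_k^T
        Vk = A[k].T @ Qk                     # tied attention: att-hat = att^T
        Hhat[k] = act(Vk) if k > 0 else Vk   # linear output layer
        Q[k] = Qk
        V[k] = Vk

    return {"H": H, "P": P, "E": E, "A": A, "U": U,
            "Q": Q, "V": V, "Hhat": Hhat, "mask": mask}


def backward(cache: dict, params: GATParams, d_recon: np.ndarray | None = None,
             d_z: np.ndarray | None = None) -> dict:
    """Analytic gradients of a scalar loss w.r.t. all parameters.

    ``d_recon`` is d loss / d Hhat[0]; ``d_z`` is any direct d loss / d z
    (e.g. through the transport cost).  Gradients flow through the tied
    decoder back into the shared weights and attention vectors.
    """
    mask = cache["mask"]
    H, P, E, A, U = cache["H"], cache["P"], cache["E"], cache["A"], cache["U"]
    Q, V, Hhat = cache["Q"], cache["V"], cache["Hhat"]
    K = params.n_layers
    _, dact = _ACTIVATIONS[params.activation]

    dW = [np.zeros_like(w) for w in params.W]
    dv_s = [np.zeros_like(v) for v in params.v_s]
    dv_r = [np.zeros_like(v) for v in params.v_r]
    GA_dec = [None] * K

    # --- decoder (bottom layer back up to the latent code) ---
    Gh = d_recon if d_recon is not None else np.zeros_like(Hhat[0])
    for k in range(K):
        GV = Gh if k == 0 else Gh * dact(V[k])
        GA_dec[k] = Q[k] @ GV.T              # V = A^T Q
        GQ = A[k] @ GV
        dW[k] += Hhat[k + 1].T @ GQ          # Q = Hhat W
        Gh = GQ @ params.W[k].T
    Gz = Gh
    if d_z is not None:
        Gz = Gz + d_z

    # --- encoder (latent layer back down to the input) ---
    G = Gz
    for k in range(K - 1, -1, -1):
        GU = G if k == K - 1 else G * dact(U[k])
        GA = GU @ P[k].T + GA_dec[k]
        GP = A[k].T @ GU
        # softmax rows: dE = A * (GA - sum_l A_il GA_il)
        GE = A[k] * (GA - (A[k] * GA).sum(axis=1, keepdims=True))
        GS = GE * E[k] * (1.0 - E[k])        # sigmoid logits, zero off-mask
        GS[~mask] = 0.0
        gs = GS.sum(axis=1)
        gr = GS.sum(axis=0)
        GP += np.outer(gs, params.v_s[k]) + np.outer(gr, params.v_r[k])
        dv_s[k] += P[k].T @ gs
        dv_r[k] += P[k].T @ gr
        dW[k] += GP.T @ H[k]                 # P = H W^T
        G = GP @ params.W[k]

    return {"W": dW, "v_s": dv_s, "v_r": dv_r, "input": G}


def encode(slices_concat: np.ndarray, graph: SpatialGraph, params: GATParams,
           slice_ids: np.ndarray | None = None) -> Embedding:
    """Latent embedding ``z`` of row-concatenated normalized expressions.

    The graph must be the block-diagonal union of per-slice graphs, so no
    information crosses slices in the forward pass.
    """
    cache = forward(slices_concat, graph, params)
    n = slices_concat.shape[0]
    ids = np.zeros(n, dtype=object) if slice_ids is None else np.asarray(slice_ids)
    return Embedding(z=cache["H"][params.n_layers], slice_ids=ids)


def decode(embedding: Embedding | np.ndarray, graph: SpatialGraph,
           params: GATParams, attentions: list[np.ndarray]) -> np.ndarray:
    """Mirror the encoder with tied weights and transposed attention.

    ``attentions`` are the per-layer encoder attention matrices (from
    ``forward``'s cache) — the tied decoder is defined relative to them.
    """
    z = embedding.z if isinstance(embedding, Embedding) else np.asarray(embedding)
    act, _ = _ACTIVATIONS[params.activation]
    K = params.n_layers
    Hhat = z
    for k in range(K - 1, -1, -1):
        Vk = attentions[k].T @ (Hhat @ params.W[k])
        Hhat = act(Vk) if k > 0 else Vk
    return Hhat


def autoencode(H0: np.ndarray, graph: SpatialGraph, params: GATParams):
    """Convenience wrapper: returns ``(z, reconstruction, cache)``."""
    cache = forward(H0, graph, params)
    return cache["H"][params.n_layers], cache["Hhat"][0], cache


def reconstruction_loss(h0: np.ndarray, h0_hat: np.ndarray) -> float:
    """Sum of squared residuals ``sum_i ||h_i - h-hat_i||^2``."""
    h0 = np.asarray(h0, dtype=float)
    h0_hat = np.asarray(h0_hat, dtype=float)
    if h0.shape != h0_hat.shape:
        raise ValueError("shapes differ")
    return float(((h0 - h0_hat) ** 2).sum())


def save_params(params: GATParams, path) -> None:
    arrays = {}
    for k in range(params.n_layers):
        arrays[f"W_{k}"] = params.W[k]
        arrays[f"vs_{k}"] = params.v_s[k]
        arrays[f"vr_{k}"] = params.v_r[k]
    np.savez(path, layer_dims=np.asarray(params.layer_dims),
             activation=np.asarray(params.activation), **arrays)


def load_params(path) -> GATParams:
    data = np.load(path, allow_pickle=False)
    layer_dims = [int(d) for d in data["layer_dims"]]
    K = len(layer_dims) - 1
    return GATParams(
        layer_dims=layer_dims,
        W=[data[f"W_{k}"] for k in range(K)],
        v_s=[data[f"vs_{k}"] for k in range(K)],
        v_r=[data[f"vr_{k}"] for k in range(K)],
        activation=str(data["activation"]),
    )
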