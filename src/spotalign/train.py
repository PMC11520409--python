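"""Joint training of the autoencoder and the transport plan.

The total objective is the trade-off

    L_total = (1 - gamma) * L_recon + gamma * L_UOT,     gamma = 0.2

optimized in an alternating (envelope-style) manner: the plan ``T`` is
re-solved from the current embeddings every ``plan_refresh_every`` epochs and
held fixed in between, so the UOT term's gradient flows only through the cost
matrix ``C`` (hence the embeddings), never through ``T``.  A reconstruction-
only warmup lets the latent space form before alignment starts.

Scaling note: the reconstruction term is averaged per matrix entry and the
transport cost is max-normalized before both the solve and the loss, so both
objective terms are O(1) and ``gamma`` is a meaningful trade-off at any spot
or gene count.  ``reconstruction_loss`` itself (the summed form) is what the
history reports after dividing by n*g.

Multi-slice integration reuses a trained network as a reference model: new
slices are encoded (optionally after a brief reconstruction-only fine-tune)
and coupled to a designated reference slice by a fresh UOT plan.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import gat
from .gat import Embedding, GATParams
from .graph import SpatialGraph, block_diagonal, build_graph, suggest_radius
from .io import STSlice
from .uot import TransportPlan, latent_cost, solve_uot

__all__ = ["TrainConfig", "IntegrationResult", "train_pair",
           "integrate_new_slice", "spatial_plan_init"]


@dataclass
class TrainConfig:
    """Training and solver settings.

    ``gamma`` is the reconstruction/alignment trade-off (0 = autoencoder
    only).  ``rho1 = inf, rho2 = 0.01`` is the partial-alignment regime in
    which every source spot ships its full mass but target spots may be
    skipped; ``rho1 = rho2 = 1`` is the default global regime.
    """

    gamma: float = 0.2
    epochs: int = 500
    lr: float = 1e-3
    plan_refresh_every: int = 10
    warmup_epochs: int = 100
    seed: int = 0
    # UOT settings
    epsilon: float = 0.05
    rho1: float = 1.0
    rho2: float = 1.0
    n_outer: int = 50
    n_inner: int = 10
    tol: float = 1e-6
    spatial_init: bool = False
    # architecture
    hidden_dims: tuple[int, ...] = (512, 30)
    activation: str = "elu"
    # graph
    radius: float | None = None
    target_mean_neighbors: float = 6.0
    # multi-slice
    reference_slice_id: str | None = None
    finetune_epochs: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def partial_mode(self) -> "TrainConfig":
        """Copy configured for partial alignment (rho1 = inf, rho2 = 0.01)."""
        cfg = TrainConfig(**{**asdict(self)})
        cfg.rho1 = float("inf")
        cfg.rho2 = 0.01
        return cfg


@dataclass
class IntegrationResult:
    embedding: Embedding
    plan: TransportPlan
    history: list  # (epoch, L_recon, L_UOT, L_total) on objective scale
    model: GATParams
    seed: int
    slice_sizes: dict  # slice_id -> n_spots

    def history_array(self) -> np.ndarray:
        return np.asarray([h[1:] for h in self.history])


class _Adam:
    """Adaptive-moment gradient descent over a list of arrays."""

    def __init__(self, arrays, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def spatial_plan_init(coords_x: np.ndarray, coords_y: np.ndarray,
                      bandwidth: float = 0.2) -> np.ndarray:
    """Optional spatially informed initial plan.

    Gaussian kernel on within-slice min-max-normalized, centered coordinates;
    gives nearby (in normalized position) spot pairs a head start.  Off by
    default: it presumes the slices are roughly pre-oriented.
    """
    def _norm(c):
        c = np.asarray(c, dtype=float)
        span = np.ptp(c, axis=0)
        span[span == 0] = 1.0
        c = (c - c.min(axis=0)) / span
        return c - c.mean(axis=0)

    cx, cy = _norm(coords_x), _norm(coords_y)
    d2 = (np.sum(cx**2, 1)[:, None] + np.sum(cy**2, 1)[None, :]
          - 2.0 * cx @ cy.T)
    K = np.exp(-np.maximum(d2, 0.0) / (2.0 * bandwidth**2))
    return K / K.sum()


def _prepare_pair(slice_x: STSlice, slice_y: STSlice,
                  graphs, config: TrainConfig):
    if slice_x.genes != slice_y.genes:
        raise ValueError("slices do not share an identical ordered gene list")
    if graphs is None:
        graphs = []
        for s in (slice_x, slice_y):
            r = config.radius or suggest_radius(
                s, config.target_mean_neighbors)
            graphs.append(build_graph(s, r))
    graph = block_diagonal(list(graphs))
    H0 = np.vstack([slice_x.expr, slice_y.expr])
    n_x = slice_x.n_spots
    slice_ids = np.array([slice_x.slice_id] * n_x
                         + [slice_y.slice_id] * slice_y.n_spots)
    return H0, graph, n_x, slice_ids


def _solve_plan(z, n_x, config: TrainConfig, T_init=None):
    C = latent_cost(z[:n_x], z[n_x:], normalize=True)
    return solve_uot(C, epsilon=config.epsilon, rho1=config.rho1,
                     rho2=config.rho2, T_init=T_init,
                     n_outer=config.n_outer, n_inner=config.n_inner,
                     tol=config.tol), C


def _uot_grad_z(z, n_x, T, scale):
    """d(sum C_ij T_ij)/dz for Euclidean C, T fixed, times ``scale``."""
    zx, zy = z[:n_x], z[n_x:]
    C = latent_cost(zx, zy).C
    Cs = np.where(C > 0, C, 1.0)
    W = (T / Cs) * scale
    dzx = W.sum(axis=1)[:, None] * zx - W @ zy
    dzy = W.sum(axis=0)[:, None] * zy - W.T @ zx
    return np.vstack([dzx, dzy])


def train_pair(slice_x: STSlice, slice_y: STSlice,
               graphs: list[SpatialGraph] | None = None,
               config: TrainConfig | None = None) -> IntegrationResult:
    """Jointly train the autoencoder and the transport plan on two slices.

    Deterministic given ``config.seed`` (full-batch, no sampling).  During
    ``warmup_epochs`` only the reconstruction term is optimized; afterwards
    the plan is re-solved every ``plan_refresh_every`` epochs from the
    current embedding and the combined objective is descended with Adam.
    With ``gamma = 0`` training reduces to the plain autoencoder and the plan
    is computed once post hoc.
    """
    config = config or TrainConfig()
    H0, graph, n_x, slice_ids = _prepare_pair(slice_x, slice_y, graphs, config)
    n, g = H0.shape
    dims = [g, *config.hidden_dims]
    params = gat.init_params(dims, seed=config.seed,
                             activation=config.activation)
    opt = _Adam(params.flat_list(), lr=config.lr)

    T_init = (spatial_plan_init(slice_x.coords, slice_y.coords)
              if config.spatial_init else None)

    T = None
    cost_scale = 1.0
    history = []
    for epoch in range(config.epochs):
        cache = gat.forward(H0, graph, params)
        z = cache["H"][params.n_layers]
        Hhat = cache["Hhat"][0]

        in_warmup = epoch < config.warmup_epochs
        gamma = 0.0 if (in_warmup or config.gamma == 0.0) else config.gamma
        if gamma > 0 and (T is None or
                          (epoch - config.warmup_epochs) % config.plan_refresh_every == 0):
            plan, Cn = _solve_plan(z, n_x, config, T_init=T_init)
            T = plan.T
            Craw = latent_cost(z[:n_x], z[n_x:]).C
            cost_scale = max(Craw.max(), 1e-12)

        L_recon = gat.reconstruction_loss(H0, Hhat) / (n * g)
        d_recon = (1.0 - gamma) * 2.0 * (Hhat - H0) / (n * g)
        if gamma > 0:
            Craw = latent_cost(z[:n_x], z[n_x:]).C
            L_uot = float((Craw * T).sum()) / cost_scale
            d_z = _uot_grad_z(z, n_x, T, gamma / cost_scale)
        else:
            L_uot = 0.0
            d_z = None
        L_total = (1.0 - gamma) * L_recon + gamma * L_uot
        if not np.isfinite(L_total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                f"L_recon={L_recon}, L_UOT={L_uot}")
        history.append((epoch, L_recon, L_uot, L_total))

        grads = gat.backward(cache, params, d_recon=d_recon, d_z=d_z)
        opt.step(params.flat_list(),
                 grads["W"] + grads["v_s"] + grads["v_r"])

    # final embedding and a plan consistent with it
    cache = gat.forward(H0, graph, params)
    z = cache["H"][params.n_layers]
    plan, _ = _solve_plan(z, n_x, config, T_init=T_init)
    return IntegrationResult(
        embedding=Embedding(z=z, slice_ids=slice_ids),
        plan=plan,
        history=history,
        model=params,
        seed=config.seed,
        slice_sizes={slice_x.slice_id: n_x, slice_y.slice_id: n - n_x},
    )


def integrate_new_slice(model: GATParams, existing: IntegrationResult,
                        new_slice: STSlice,
                        new_graph: SpatialGraph | None = None,
                        config: TrainConfig | None = None) -> IntegrationResult:
    """Append a slice to an existing integration using the reference model.

    The new slice is encoded with the trained network, optionally after
    ``finetune_epochs`` of reconstruction-only adaptation on the new slice
    alone (0 = frozen model, parameters bit-identical).  A UOT plan couples
    the new slice to the designated reference slice's existing embedding
    rows; the existing embedding is left untouched.
    """
    config = config or TrainConfig()
    if new_slice.n_genes != model.layer_dims[0]:
        raise ValueError(
            f"new slice has {new_slice.n_genes} genes; the reference model "
            f"expects {model.layer_dims[0]}")
    if new_graph is None:
        r = config.radius or suggest_radius(new_slice,
                                            config.target_mean_neighbors)
        new_graph = build_graph(new_slice, r)

    params = model.copy()
    if config.finetune_epochs > 0:
        opt = _Adam(params.flat_list(), lr=config.lr)
        n, g = new_slice.expr.shape
        for _ in range(config.finetune_epochs):
            cache = gat.forward(new_slice.expr, new_graph, params)
            d_recon = 2.0 * (cache["Hhat"][0] - new_slice.expr) / (n * g)
            grads = gat.backward(cache, params, d_recon=d_recon)
            opt.step(params.flat_list(),
                     grads["W"] + grads["v_s"] + grads["v_r"])

    z_new = gat.encode(new_slice.expr, new_graph, params,
                       slice_ids=np.array([new_slice.slice_id]
                                          * new_slice.n_spots)).z

    ref_id = config.reference_slice_id or next(iter(existing.slice_sizes))
    ids = np.asarray(existing.embedding.slice_ids)
    if ref_id not in ids:
        raise ValueError(f"reference slice {ref_id!r} not in the integration")
    z_ref = existing.embedding.z[ids == ref_id]

    C = latent_cost(z_new, z_ref, normalize=True)
    plan = solve_uot(C, epsilon=config.epsilon, rho1=config.rho1,
                     rho2=config.rho2, n_outer=config.n_outer,
                     n_inner=config.n_inner, tol=config.tol)

    embedding = Embedding(
        z=np.vstack([existing.embedding.z, z_new]),
        slice_ids=np.concatenate([ids,
                                  np.array([new_slice.slice_id]
                                           * new_slice.n_spots)]),
    )
    sizes = dict(existing.slice_sizes)
    sizes[new_slice.slice_id] = new_slice.n_spots
    return IntegrationResult(embedding=embedding, plan=plan,
                             history=list(existing.history), model=params,
                             seed=config.seed, slice_sizes=sizes)
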