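"""Synthetic paired/multi-slice ST data with planted ground truth.

The generator emulates the structure of layered cortical tissue: spots on a
regular grid, cell-type labels in horizontal bands (layers), each layer with
its own marker genes whose mean is elevated by ``layer_effect`` on the
log-normalized scale.  On top of the biology it plants the nuisances the
integration method must undo:

* a per-slice batch effect (additive shift on a random 30% gene subset),
* a rigid rotation/translation of the second slice's coordinates,
* optional partial crops (oblique to the bands) with configurable overlap.

The non-marker genes carry smooth positional gradients: a lateral (x) one and
a depth (y) one.  Real tissue is not mirror-symmetric, and without positional
expression variation a band-structured slice is geometrically unidentifiable
(any x-mirror is expression-preserving), so registration from expression
alone would be ill-posed rather than merely hard; the depth gradient gives
adjacent layers the graded similarity real cortical layers have.

Expression is additive Gaussian on the log-normalized scale — the scale the
model consumes.  A count mode (Poisson with an exponential link) exists to
exercise the normalization pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import STSlice

__all__ = ["SyntheticConfig", "make_layered_pair", "make_partial_pair",
           "make_multi_stack", "rotate"]


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults are the package's study conditions.

    ``layer_effect`` and ``noise_sd`` are in log-normalized expression
    units; ``rotation_deg``/``translation`` act on slice 2's coordinates
    (grid units, spacing 1); ``overlap_fraction`` is the fraction of spots
    each partial crop keeps (0.7 means the two crops share 40% of spots).
    """

    grid_shape: tuple[int, int] = (20, 20)
    n_layers: int = 4
    genes_per_layer: int = 15
    g_total: int = 80
    layer_effect: float = 1.0
    gradient_effect: float = 1.0
    batch_shift: float = 0.5
    batch_gene_frac: float = 0.3
    noise_sd: float = 0.3
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    overlap_fraction: float = 0.7
    counts_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid must be nonempty")
        if self.n_layers > rows:
            raise ValueError("more layers than grid rows")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.g_total < self.n_layers * self.genes_per_layer + 1:
            raise ValueError(
                "g_total too small for the marker blocks plus gradient genes")
        if self.noise_sd < 0 or self.batch_shift < 0:
            raise ValueError("noise_sd and batch_shift must be nonnegative")


def rotate(coords: np.ndarray, degrees: float,
           translation=(0.0, 0.0)) -> np.ndarray:
    """Rotate 2D coordinates about their centroid, then translate."""
    theta = np.deg2rad(degrees)
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    center = coords.mean(axis=0)
    return (coords - center) @ R.T + center + np.asarray(translation, float)


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(cols, dtype=float),
                         np.arange(rows, dtype=float))
    return np.column_stack([xx.ravel(), yy.ravel()])


def _layer_labels(coords: np.ndarray, rows: int, n_layers: int) -> np.ndarray:
    band = np.minimum((coords[:, 1] * n_layers / rows).astype(int),
                      n_layers - 1)
    return np.array([f"layer_{b}" for b in band])


def _base_signal(cfg: SyntheticConfig, coords: np.ndarray,
                 labels: np.ndarray) -> np.ndarray:
    """Deterministic spot x gene mean: baseline + markers + position gradients.

    The non-marker genes split into a lateral (x) and a depth (y) gradient
    block.  The lateral gradient makes the geometry identifiable (tissue is
    not mirror-symmetric); the depth gradient makes *adjacent* layers more
    similar than distant ones, the graded transcriptional structure of real
    cortical depth.  Marker-gene means still differ between layers by exactly
    ``layer_effect`` in expectation.
    """
    n = coords.shape[0]
    mu = np.full((n, cfg.g_total), 0.5)
    for layer in range(cfg.n_layers):
        sel = labels == f"layer_{layer}"
        lo = layer * cfg.genes_per_layer
        mu[np.ix_(sel, np.arange(lo, lo + cfg.genes_per_layer))] += cfg.layer_effect
    free = cfg.g_total - cfg.n_layers * cfg.genes_per_layer
    n_x = max(1, free // 2)
    n_y = max(0, free - n_x)
    for axis, n_grad, sl in ((0, n_x, slice(cfg.g_total - n_x, cfg.g_total)),
                             (1, n_y, slice(cfg.g_total - n_x - n_y,
                                            cfg.g_total - n_x))):
        if n_grad == 0:
            continue
        c = coords[:, axis]
        span = np.ptp(c) if np.ptp(c) > 0 else 1.0
        mu[:, sl] += cfg.gradient_effect * ((c - c.min()) / span)[:, None]
    return mu


def _gene_names(cfg: SyntheticConfig) -> list[str]:
    return [f"gene_{i:04d}" for i in range(cfg.g_total)]


def _emit(cfg: SyntheticConfig, mu: np.ndarray, rng: np.random.RandomState,
          batch_shift_vec: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Noisy expression (and counts in count mode) from a mean matrix."""
    shifted = mu + batch_shift_vec[None, :]
    if cfg.counts_mode:
        lam = np.exp(shifted)
        counts = rng.poisson(lam).astype(float)
        return np.log1p(counts), counts
    expr = shifted + rng.normal(0.0, cfg.noise_sd, size=mu.shape)
    return expr, None


def _batch_vector(cfg: SyntheticConfig, rng: np.random.RandomState,
                  magnitude: float) -> np.ndarray:
    v = np.zeros(cfg.g_total)
    if magnitude > 0:
        k = max(1, int(round(cfg.batch_gene_frac * cfg.g_total)))
        genes = rng.choice(cfg.g_total, size=k, replace=False)
        v[genes] = magnitude
    return v


def _make_slice(cfg: SyntheticConfig, slice_id: str, coords: np.ndarray,
                labels: np.ndarray, mu: np.ndarray,
                rng: np.random.RandomState, batch_vec: np.ndarray) -> STSlice:
    expr, counts = _emit(cfg, mu, rng, batch_vec)
    return STSlice(slice_id=slice_id, expr=expr, coords=coords,
                   genes=_gene_names(cfg), labels=labels,
                   raw_counts=counts,
                   raw_genes=_gene_names(cfg) if counts is not None else None)


def make_layered_pair(cfg: SyntheticConfig):
    """Two replicate slices of one layered tissue.

    Slice 2 re-measures the same spots (fresh noise, its own batch shift) and
    its coordinates are slice 1's after the configured rigid motion.  The
    ground-truth correspondence is the identity.
    """
    cfg.validate()
    rng = np.random.RandomState(cfg.seed)
    rows, cols = cfg.grid_shape
    coords = _grid_coords(rows, cols)
    labels = _layer_labels(coords, rows, cfg.n_layers)
    mu = _base_signal(cfg, coords, labels)

    s1 = _make_slice(cfg, "slice_1", coords, labels, mu, rng,
                     np.zeros(cfg.g_total))
    batch2 = _batch_vector(cfg, rng, cfg.batch_shift)
    coords2 = rotate(coords, cfg.rotation_deg, cfg.translation)
    s2 = _make_slice(cfg, "slice_2", coords2, labels, mu, rng, batch2)
    truth = np.arange(coords.shape[0])
    return s1, s2, truth


def make_partial_pair(cfg: SyntheticConfig):
    """Two partially overlapping straight-line crops of a layered tissue.

    Each crop keeps ``overlap_fraction`` of the spots: the lower crop from
    replicate 1, the upper crop from replicate 2 (which carries the batch
    shift and the rigid motion).  The crop lines run *obliquely* across the
    layer bands, so every layer is present in both subslices but in different
    proportions — the situation straight crop lines create when they cross
    curved cortical layers in real tissue, and the one the unbalanced
    (partial) transport regime exists for: a balanced coupling must distort
    the proportions, a partial one may leave surplus spots unmatched.
    Ground truth is defined on the shared middle band only and is returned
    as an (index-in-lower, index-in-upper) pair array.
    """
    cfg.validate()
    if cfg.overlap_fraction <= 0.5:
        raise ValueError(
            "overlap_fraction <= 0.5 leaves no shared spots between crops")
    s1, s2, _ = make_layered_pair(cfg)
    n = s1.n_spots
    # stable order along an oblique (45 degree) axis on slice 1's
    # untransformed geometry
    score = s1.coords[:, 0] + s1.coords[:, 1]
    order = np.lexsort((s1.coords[:, 0], s1.coords[:, 1], score))
    k = int(round(cfg.overlap_fraction * n))
    left_idx = np.sort(order[:k])
    right_idx = np.sort(order[n - k:])

    def _crop(s: STSlice, idx: np.ndarray, sid: str) -> STSlice:
        return STSlice(slice_id=sid, expr=s.expr[idx], coords=s.coords[idx],
                       genes=s.genes,
                       labels=None if s.labels is None else s.labels[idx],
                       raw_counts=None if s.raw_counts is None else s.raw_counts[idx],
                       raw_genes=s.raw_genes)

    left = _crop(s1, left_idx, "lower")
    right = _crop(s2, right_idx, "upper")
    shared = np.intersect1d(left_idx, right_idx)
    pos_left = np.searchsorted(left_idx, shared)
    pos_right = np.searchsorted(right_idx, shared)
    truth = np.column_stack([pos_left, pos_right])
    return left, right, truth


def make_multi_stack(cfg: SyntheticConfig, n_slices: int = 3,
                     label_drift: bool = False):
    """``n_slices`` replicates with independent batch shifts and motions.

    With ``label_drift`` each successive slice subdivides the bottom layer
    once more, so the label-set size strictly increases along the stack
    (emulating developmental series in which cell types accumulate).
    Returns (slices, identity ground-truth indices).
    """
    cfg.validate()
    if n_slices < 2:
        raise ValueError("need at least two slices")
    rng = np.random.RandomState(cfg.seed)
    rows, cols = cfg.grid_shape
    coords = _grid_coords(rows, cols)
    labels = _layer_labels(coords, rows, cfg.n_layers)
    mu = _base_signal(cfg, coords, labels)

    slices = []
    for s_idx in range(n_slices):
        batch = (np.zeros(cfg.g_total) if s_idx == 0
                 else _batch_vector(cfg, rng, cfg.batch_shift))
        angle = float(rng.uniform(-180, 180)) if s_idx > 0 else 0.0
        shift = rng.uniform(-5, 5, size=2) if s_idx > 0 else np.zeros(2)
        coords_s = rotate(coords, angle, shift) if s_idx > 0 else coords
        lab = labels.astype(object)
        if label_drift and s_idx > 0:
            # subdivide layer_0 into s_idx+1 sub-bands by y within the band
            sel = labels == "layer_0"
            y = coords[sel, 1]
            edges = np.linspace(y.min(), y.max() + 1e-9, s_idx + 2)
            sub = np.digitize(y, edges[1:-1])
            lab[sel] = np.array([f"layer_0.{b}" for b in sub], dtype=object)
        lab = lab.astype(str)
        slices.append(_make_slice(cfg, f"slice_{s_idx + 1}", coords_s, lab,
                                  mu, rng, batch))
    truth = np.arange(coords.shape[0])
    return slices, truth
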