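"""Reading, writing and preprocessing of spatial transcriptomics slices.

A slice is a spot x gene expression matrix with per-spot 2D coordinates and
optional categorical annotations.  Supported on-disk forms:

* AnnData ``.h5ad`` — expression in ``X`` (raw counts kept when integral),
  coordinates in a named 2-column ``obsm`` field, labels in ``obs``;
* MatrixMarket — a directory with ``matrix.mtx`` (spots x genes),
  ``genes.tsv`` (one gene per line) and ``coords.tsv``
  (columns ``spot_id``, ``x``, ``y`` and optionally ``label``);
* dense CSV — a directory with ``expr.csv`` (spots x genes, header = gene
  names, index = spot ids) and the same ``coords.tsv``.

``normalize_and_intersect`` produces the model inputs: library-size scaling
to a common target sum, log1p, and a deterministic highly-variable-gene
selection on the slices' shared gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """File does not contain the declared structure."""


class ValidationError(ValueError):
    """Values are present but invalid (non-numeric, non-finite, ...)."""


class ShapeError(ValueError):
    """Component dimensions disagree."""


@dataclass
class STSlice:
    """One spatial transcriptomics slice.

    ``expr`` is spot x gene on the normalized (log) scale; ``raw_counts``
    preserves the integer counts when available so preprocessing can be
    re-derived.  All slices entering one analysis must share an identical
    ordered gene list after pairing.
    """

    slice_id: str
    expr: np.ndarray
    coords: np.ndarray
    genes: list[str]
    labels: np.ndarray | None = None
    raw_counts: np.ndarray | None = None
    raw_genes: list[str] | None = None

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        try:
            self.coords = np.asarray(self.coords, dtype=float)
        except (TypeError, ValueError) as err:
            raise ValidationError(f"non-numeric coordinates: {err}") from err
        if self.expr.ndim != 2 or self.expr.shape[0] < 1 or self.expr.shape[1] < 1:
            raise ShapeError("expression must be a nonempty 2-D matrix")
        if not np.all(np.isfinite(self.expr)):
            raise ValidationError("expression has NaN/Inf entries")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ShapeError("coordinates must have exactly 2 columns")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if self.coords.shape[0] != self.expr.shape[0]:
            raise ShapeError(
                f"{self.coords.shape[0]} coordinate rows vs "
                f"{self.expr.shape[0]} expression rows")
        if len(self.genes) != self.expr.shape[1]:
            raise ShapeError("gene list length does not match expression")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_spots:
                raise ShapeError("labels length does not match spot count")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def scaled_coords(self, mode: str | None = None) -> np.ndarray:
        """Optionally min-max or z-scale coordinates (radius convenience)."""
        if mode is None:
            return self.coords
        c = self.coords
        if mode == "minmax":
            span = np.ptp(c, axis=0)
            span[span == 0] = 1.0
            return (c - c.min(axis=0)) / span
        if mode == "zscore":
            sd = c.std(axis=0)
            sd[sd == 0] = 1.0
            return (c - c.mean(axis=0)) / sd
        raise ValueError(f"unknown coordinate scaling {mode!r}")

    def to_anndata(self, spatial_key: str = "spatial",
                   label_key: str = "label") -> ad.AnnData:
        adata = ad.AnnData(
            X=self.expr.copy(),
            obs=pd.DataFrame(index=[f"spot_{i}" for i in range(self.n_spots)]),
            var=pd.DataFrame(index=list(self.genes)),
        )
        adata.obsm[spatial_key] = self.coords.copy()
        if self.labels is not None:
            adata.obs[label_key] = pd.Categorical(self.labels)
        if self.raw_counts is not None:
            raw_genes = self.raw_genes if self.raw_genes is not None else self.genes
            adata.uns["raw_genes"] = list(raw_genes)
            adata.obsm["raw_counts"] = np.asarray(self.raw_counts)
        adata.uns["slice_id"] = self.slice_id
        return adata


def _looks_like_counts(X: np.ndarray) -> bool:
    return bool(np.all(X >= 0) and np.allclose(X, np.round(X)))


def from_anndata(adata: ad.AnnData, slice_id: str | None = None,
                 spatial_key: str = "spatial",
                 label_key: str | None = None) -> STSlice:
    if spatial_key not in adata.obsm:
        raise FormatError(f"missing spatial field {spatial_key!r} in obsm")
    coords = np.asarray(adata.obsm[spatial_key])
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise FormatError(f"spatial field {spatial_key!r} must have 2 columns")
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    X = X.astype(float)
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise FormatError(f"missing label column {label_key!r} in obs")
        labels = np.asarray(adata.obs[label_key].astype(str))
    raw = None
    raw_genes = None
    if "counts" in adata.layers:
        raw = np.asarray(adata.layers["counts"].toarray()
                         if sp.issparse(adata.layers["counts"])
                         else adata.layers["counts"], dtype=float)
        raw_genes = list(adata.var_names)
    elif "raw_counts" in adata.obsm:
        raw = np.asarray(adata.obsm["raw_counts"], dtype=float)
        raw_genes = list(adata.uns.get("raw_genes", adata.var_names))
    elif _looks_like_counts(X):
        raw = X.copy()
        raw_genes = list(adata.var_names)
    sid = slice_id or str(adata.uns.get("slice_id", "slice"))
    return STSlice(slice_id=sid, expr=X, coords=coords,
                   genes=list(adata.var_names), labels=labels,
                   raw_counts=raw, raw_genes=raw_genes)


def _read_coords_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing coordinate table {path}")
    tab = pd.read_csv(path, sep="\t")
    for col in ("x", "y"):
        if col not in tab.columns:
            raise FormatError(f"coordinate table lacks column {col!r}")
        if not pd.api.types.is_numeric_dtype(tab[col]):
            raise ValidationError(f"non-numeric coordinate column {col!r}")
    return tab


def load_slice(path, format: str = "h5ad", spatial_key: str = "spatial",
               label_key: str | None = None,
               slice_id: str | None = None) -> STSlice:
    """Load one slice from disk.

    ``format`` is one of ``h5ad``, ``mtx+tsv``, ``csv`` (the latter two read
    a directory; see module docstring for the layout).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = slice_id or path.stem

    if format == "h5ad":
        return from_anndata(ad.read_h5ad(path), slice_id=sid,
                            spatial_key=spatial_key, label_key=label_key)

    if format not in ("mtx+tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")

    coords_tab = _read_coords_table(path / "coords.tsv")
    if format == "mtx+tsv":
        mtx_path = path / "matrix.mtx"
        genes_path = path / "genes.tsv"
        if not mtx_path.exists() or not genes_path.exists():
            raise FormatError(f"{path} lacks matrix.mtx/genes.tsv")
        X = scipy.io.mmread(mtx_path)
        X = X.toarray() if sp.issparse(X) else np.asarray(X)
        genes = [ln.strip() for ln in genes_path.read_text().splitlines() if ln.strip()]
    else:
        csv_path = path / "expr.csv"
        if not csv_path.exists():
            raise FormatError(f"{path} lacks expr.csv")
        tab = pd.read_csv(csv_path, index_col=0)
        X = tab.to_numpy(dtype=float)
        genes = list(tab.columns)

    if coords_tab.shape[0] != X.shape[0]:
        raise ShapeError(
            f"{coords_tab.shape[0]} coordinate rows vs {X.shape[0]} matrix rows")
    labels = None
    if "label" in coords_tab.columns:
        labels = coords_tab["label"].astype(str).to_numpy()
    X = np.asarray(X, dtype=float)
    raw = X.copy() if _looks_like_counts(X) else None
    return STSlice(slice_id=sid, expr=X,
                   coords=coords_tab[["x", "y"]].to_numpy(dtype=float),
                   genes=genes, labels=labels, raw_counts=raw,
                   raw_genes=genes if raw is not None else None)


def save_slice(slc: STSlice, path, spatial_key: str = "spatial",
               label_key: str = "label",
               embedding: np.ndarray | None = None,
               plan_meta: dict | None = None) -> None:
    """Write a slice as h5ad, optionally with an embedding and plan metadata."""
    adata = slc.to_anndata(spatial_key=spatial_key, label_key=label_key)
    if embedding is not None:
        adata.obsm["X_spotalign"] = np.asarray(embedding)
    if plan_meta is not None:
        adata.uns["spotalign_plan"] = plan_meta
    adata.write_h5ad(Path(path))


def save_slice_mtx(slc: STSlice, outdir) -> None:
    """Write a slice as MatrixMarket + TSV (exercises the text reader)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = slc.raw_counts if slc.raw_counts is not None else slc.expr
    genes = slc.raw_genes if slc.raw_counts is not None else slc.genes
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(mat))
    (outdir / "genes.tsv").write_text("\n".join(genes) + "\n")
    tab = pd.DataFrame({
        "spot_id": [f"spot_{i}" for i in range(slc.n_spots)],
        "x": slc.coords[:, 0],
        "y": slc.coords[:, 1],
    })
    if slc.labels is not None:
        tab["label"] = slc.labels
    tab.to_csv(outdir / "coords.tsv", sep="\t", index=False)


def intersect_genes(slices: list[STSlice]) -> list[STSlice]:
    """Restrict pre-normalized slices to their shared, lexicographically
    ordered gene list (for inputs that carry no raw counts)."""
    shared = set(slices[0].genes)
    for s in slices[1:]:
        shared &= set(s.genes)
    if not shared:
        raise ValidationError("slices share no genes")
    order = sorted(shared)
    out = []
    for s in slices:
        idx = [s.genes.index(g) for g in order]
        out.append(STSlice(slice_id=s.slice_id, expr=s.expr[:, idx],
                           coords=s.coords, genes=order, labels=s.labels,
                           raw_counts=s.raw_counts, raw_genes=s.raw_genes))
    return out


def normalize_and_intersect(slices: list[STSlice], n_hvg: int = 3000,
                            target_sum: float = 1e4) -> list[STSlice]:
    """Normalize raw counts and select shared highly variable genes.

    Per spot: library-size scaling to ``target_sum`` then log1p.  HVGs are
    computed per slice on the shared gene set; genes are ranked by how many
    slices select them, ties broken by mean dispersion, and the top
    ``n_hvg`` kept in lexicographic order — a deterministic selection that
    is symmetric in the slices.
    """
    if len(slices) < 2:
        raise ValueError("need at least two slices")
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    for s in slices:
        if s.raw_counts is None:
            raise ValidationError(
                f"slice {s.slice_id!r} has no raw counts to normalize")

    shared = set(slices[0].raw_genes or slices[0].genes)
    for s in slices[1:]:
        shared &= set(s.raw_genes or s.genes)
    if not shared:
        raise ValidationError("gene intersection is empty")
    shared = sorted(shared)

    adatas = []
    for s in slices:
        genes = s.raw_genes or s.genes
        idx = [genes.index(g) for g in shared]
        counts = np.asarray(s.raw_counts, dtype=float)[:, idx]
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            raise ValidationError(
                f"slice {s.slice_id!r} has spots with zero total count")
        a = ad.AnnData(X=counts, var=pd.DataFrame(index=shared))
        sc.pp.normalize_total(a, target_sum=target_sum)
        sc.pp.log1p(a)
        adatas.append(a)

    votes = np.zeros(len(shared), dtype=int)
    disp = np.zeros(len(shared))
    k = min(n_hvg, len(shared))
    for a in adatas:
        try:
            sc.pp.highly_variable_genes(a, n_top_genes=k, flavor="seurat")
            votes += a.var["highly_variable"].to_numpy().astype(int)
            disp += np.nan_to_num(a.var["dispersions_norm"].to_numpy())
        except Exception:
            # tiny fixtures can defeat the binned dispersion estimate;
            # fall back to plain per-gene variance ranking
            v = a.X.var(axis=0)
            top = np.argsort(v)[::-1][:k]
            sel = np.zeros(len(shared), dtype=int)
            sel[top] = 1
            votes += sel
            disp += v
    disp /= len(adatas)

    order = np.lexsort((np.asarray(shared), -disp, -votes))
    keep = sorted(np.asarray(shared)[order[:k]])

    out = []
    for s, a in zip(slices, adatas):
        idx = [shared.index(g) for g in keep]
        out.append(STSlice(slice_id=s.slice_id, expr=np.asarray(a.X)[:, idx],
                           coords=s.coords, genes=list(keep), labels=s.labels,
                           raw_counts=s.raw_counts, raw_genes=s.raw_genes))
    return out
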