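"""Loading, validation, and preprocessing of paired scRNA / scATAC matrices.

Both modalities are carried as dense cells-by-features float64 arrays inside a
:class:`MultimodalDataset`.  Readers exist for three on-disk layouts:

* ``csv`` — one dense CSV per modality, header row = feature names, first
  column = cell identifiers;
* ``mtx`` — a MatrixMarket coordinate file per modality with plain-text
  ``barcodes.tsv`` / ``features.tsv`` sidecars in the same directory
  (features-by-cells orientation is detected from the barcode count and
  transposed);
* ``h5ad`` — one AnnData container per modality.

Preprocessing mirrors the common single-cell recipe: per-modality selection of
the highest-dispersion features followed by library-size normalization and
log1p.  Dispersion is the variance of the log1p-normalized values; ties are
broken by ascending column index so selection is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix, issparse

logger = logging.getLogger(__name__)

__all__ = [
    "MultimodalDataset",
    "DimensionError",
    "FormatError",
    "load_dataset",
    "save_dataset",
    "preprocess",
]


class DimensionError(ValueError):
    """Row/length mismatch between paired inputs."""


class FormatError(ValueError):
    """A file could not be parsed in the requested format."""


@dataclass
class MultimodalDataset:
    """Paired expression (RNA) and accessibility (ATAC) profiles over the same cells.

    Rows of ``x_rna`` and ``x_atac`` refer to the same cells in the same
    order.  ``labels``, when present, are ground-truth cluster indices used
    only for evaluation.
    """

    x_rna: np.ndarray
    x_atac: np.ndarray
    labels: np.ndarray | None = None
    cell_ids: list[str] = field(default_factory=list)
    n_clusters: int | None = None
    rna_features: list[str] = field(default_factory=list)
    atac_features: list[str] = field(default_factory=list)
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.x_rna = np.asarray(self.x_rna, dtype=np.float64)
        self.x_atac = np.asarray(self.x_atac, dtype=np.float64)
        if self.x_rna.ndim != 2 or self.x_atac.ndim != 2:
            raise DimensionError("modality matrices must be 2-D (cells x features)")
        if self.x_rna.shape[0] != self.x_atac.shape[0]:
            raise DimensionError(
                f"modalities cover different cells: RNA {self.x_rna.shape} "
                f"vs ATAC {self.x_atac.shape}"
            )
        if not np.isfinite(self.x_rna).all() or not np.isfinite(self.x_atac).all():
            raise ValueError("non-finite entries in input matrices")
        n = self.x_rna.shape[0]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i:05d}" for i in range(n)]
        if len(self.cell_ids) != n:
            raise DimensionError(f"{len(self.cell_ids)} cell ids for {n} cells")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise DimensionError(
                    f"labels length {self.labels.shape[0]} does not match {n} cells"
                )
            if not np.issubdtype(self.labels.dtype, np.integer):
                as_int = self.labels.astype(np.int64)
                if not np.array_equal(as_int, self.labels.astype(np.float64)):
                    raise ValueError("labels must be integers")
                self.labels = as_int
            if (self.labels < 0).any():
                raise ValueError("labels must be non-negative")
            if self.n_clusters is None:
                self.n_clusters = int(np.unique(self.labels).size)
        if not self.rna_features:
            self.rna_features = [f"rna_{j}" for j in range(self.x_rna.shape[1])]
        if not self.atac_features:
            self.atac_features = [f"atac_{j}" for j in range(self.x_atac.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.x_rna.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n cells, d1, d2)."""
        return (self.x_rna.shape[0], self.x_rna.shape[1], self.x_atac.shape[1])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    try:
        df = pd.read_csv(path, index_col=0)
        matrix = df.to_numpy(dtype=np.float64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {path} as a dense CSV matrix: {exc}") from exc
    return matrix, [str(i) for i in df.index], [str(c) for c in df.columns]


def _read_sidecar(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"MTX sidecar {path} ({what}) not found")
    return [line.split("\t")[0] for line in path.read_text().splitlines() if line]


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    try:
        matrix = mmread(path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse {path} as MatrixMarket: {exc}") from exc
    matrix = matrix.toarray() if issparse(matrix) else np.asarray(matrix)
    barcodes = _read_sidecar(path.parent / "barcodes.tsv", "cell barcodes")
    features = _read_sidecar(path.parent / "features.tsv", "feature names")
    if matrix.shape[0] != len(barcodes) and matrix.shape[1] == len(barcodes):
        logger.info(
            "%s is features x cells (%s); transposing to cells x features",
            path, matrix.shape,
        )
        matrix = matrix.T
    if matrix.shape != (len(barcodes), len(features)):
        raise DimensionError(
            f"{path}: matrix {matrix.shape} inconsistent with "
            f"{len(barcodes)} barcodes / {len(features)} features"
        )
    return np.asarray(matrix, dtype=np.float64), barcodes, features


def _read_h5ad(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    import anndata

    try:
        adata = anndata.read_h5ad(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as H5AD: {exc}") from exc
    x = adata.X
    x = x.toarray() if issparse(x) else np.asarray(x)
    return (
        np.asarray(x, dtype=np.float64),
        [str(i) for i in adata.obs_names],
        [str(v) for v in adata.var_names],
    )


_READERS = {"csv": _read_csv, "mtx": _read_mtx, "h5ad": _read_h5ad}


def _read_labels(path: Path, n: int) -> np.ndarray:
    raw = [line for line in Path(path).read_text().splitlines() if line.strip()]
    if raw and not raw[0].lstrip("-").isdigit():
        raw = raw[1:]  # header line
    labels = np.array([int(v) for v in raw], dtype=np.int64)
    if labels.shape[0] != n:
        raise DimensionError(f"labels file has {labels.shape[0]} rows for {n} cells")
    return labels


def load_dataset(
    rna_path: str | Path,
    atac_path: str | Path,
    labels_path: str | Path | None = None,
    format: str = "csv",
    n_clusters: int | None = None,
) -> MultimodalDataset:
    """Read both modality matrices (and optional labels) into a validated dataset.

    Raw values are preserved as read; call :func:`preprocess` afterwards.
    """
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    reader = _READERS[format]
    for p in (rna_path, atac_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    x_rna, rna_cells, rna_feats = reader(Path(rna_path))
    x_atac, atac_cells, atac_feats = reader(Path(atac_path))
    if x_rna.shape[0] != x_atac.shape[0]:
        raise DimensionError(
            f"RNA matrix has {x_rna.shape[0]} cells but ATAC has {x_atac.shape[0]} "
            f"(shapes {x_rna.shape} vs {x_atac.shape})"
        )
    labels = _read_labels(Path(labels_path), x_rna.shape[0]) if labels_path else None
    return MultimodalDataset(
        x_rna=x_rna,
        x_atac=x_atac,
        labels=labels,
        cell_ids=rna_cells,
        n_clusters=n_clusters,
        rna_features=rna_feats,
        atac_features=atac_feats,
    )


def save_dataset(ds: MultimodalDataset, outdir: str | Path, format: str = "csv") -> None:
    """Write a dataset in a layout :func:`load_dataset` reads back identically.

    CSV: ``rna.csv`` / ``atac.csv``.  MTX: per-modality subdirectories each
    holding ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``.  Labels, when
    present, go to ``labels.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    modalities = {
        "rna": (ds.x_rna, ds.rna_features),
        "atac": (ds.x_atac, ds.atac_features),
    }
    if format == "csv":
        for name, (x, feats) in modalities.items():
            pd.DataFrame(x, index=ds.cell_ids, columns=feats).to_csv(outdir / f"{name}.csv")
    elif format == "mtx":
        for name, (x, feats) in modalities.items():
            sub = outdir / name
            sub.mkdir(exist_ok=True)
            mmwrite(sub / "matrix.mtx", csr_matrix(x))
            (sub / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
            (sub / "features.tsv").write_text("\n".join(feats) + "\n")
    else:
        raise ValueError(f"unsupported output format {format!r}")
    if ds.labels is not None:
        np.savetxt(outdir / "labels.txt", ds.labels, fmt="%d")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _normalize_log1p(x: np.ndarray) -> np.ndarray:
    """Library-size normalize rows to the median depth, then log1p."""
    lib = x.sum(axis=1)
    if (lib <= 0).any():
        logger.warning(
            "%d cell(s) have zero total counts; library size floored at 1",
            int((lib <= 0).sum()),
        )
        lib = np.maximum(lib, 1.0)
    target = float(np.median(lib))
    return np.log1p(x / lib[:, None] * target)


def _select_features(normed: np.ndarray, n_top: int) -> np.ndarray:
    """Indices (ascending) of the ``n_top`` highest-dispersion columns.

    Dispersion is the per-column variance of the log1p-normalized matrix;
    ties break toward the lower column index.
    """
    if normed.shape[1] <= n_top:
        return np.arange(normed.shape[1])
    disp = normed.var(axis=0)
    # lexsort: primary key -disp, ties by ascending column index
    order = np.lexsort((np.arange(normed.shape[1]), -disp))
    return np.sort(order[:n_top])


def preprocess(
    ds: MultimodalDataset,
    n_top_features: int = 2000,
    normalize: bool = True,
    binarize_atac: bool = False,
) -> MultimodalDataset:
    """Reduce each modality to its top-dispersion features and normalize.

    Each modality independently keeps its ``n_top_features`` highest-dispersion
    columns (all columns if fewer exist); with ``normalize`` the retained
    counts are library-size normalized and log1p-transformed.  A dataset that
    has already been preprocessed is returned unchanged, making the operation
    idempotent.
    """
    if ds.preprocessed:
        return replace(ds)
    if (ds.x_rna < 0).any() or (ds.x_atac < 0).any():
        raise ValueError("preprocess expects non-negative raw matrices")
    x_atac_in = (ds.x_atac > 0).astype(np.float64) if binarize_atac else ds.x_atac

    out_x, out_feats = [], []
    for x, feats in ((ds.x_rna, ds.rna_features), (x_atac_in, ds.atac_features)):
        normed = _normalize_log1p(x)
        idx = _select_features(normed, n_top_features)
        out_x.append(normed[:, idx] if normalize else x[:, idx].copy())
        out_feats.append([feats[j] for j in idx])

    return MultimodalDataset(
        x_rna=out_x[0],
        x_atac=out_x[1],
        labels=None if ds.labels is None else ds.labels.copy(),
        cell_ids=list(ds.cell_ids),
        n_clusters=ds.n_clusters,
        rna_features=out_feats[0],
        atac_features=out_feats[1],
        preprocessed=True,
    )
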