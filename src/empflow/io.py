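"""Count-matrix I/O, cell-calling QC and hashtag demultiplexing.

Reads and writes CellRanger-style MTX bundles (matrix.mtx + barcodes.tsv +
features.tsv, gzip-tolerant, genes-as-rows or cells-as-rows dialect), and
implements strict-threshold cell calling — cells are kept only with *more
than* the UMI / housekeeper / gene thresholds and *less than* the
mitochondrial bound — plus manual-threshold HTO demultiplexing with
doublet removal.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .errors import ConfigurationError, FormatError


# --------------------------------------------------------------------------
# QC profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QCProfile:
    """Strict (exclusive) cell-calling thresholds.

    A cell passes iff ``total_umis > min_umis`` AND
    ``mito_fraction < max_mito_fraction`` AND, where set,
    ``n_housekeepers > min_housekeepers`` and ``n_genes > min_genes``.
    ``None`` disables a criterion.
    """

    min_umis: int | None = 500
    max_mito_fraction: float = 0.10
    min_housekeepers: int | None = None
    min_genes: int | None = None

    def __post_init__(self):
        if self.min_umis is not None and self.min_umis < 0:
            raise ConfigurationError("min_umis must be non-negative")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ConfigurationError("max_mito_fraction must lie in [0, 1]")


#: Named profiles: ``default`` (UMIs > 500, mito < 10%), ``hk30`` adds the
#: housekeeper rule used for two patients of the cohort design
#: (> 30 housekeepers), ``kurten`` is the reanalysis profile for the public
#: HNSCC dataset (> 175 genes, mito < 10%, > 60 housekeepers, no UMI cut).
QC_PROFILES = {
    "default": QCProfile(),
    "hk30": QCProfile(min_housekeepers=30),
    "kurten": QCProfile(min_umis=None, min_genes=175, min_housekeepers=60),
}


# --------------------------------------------------------------------------
# MTX bundle reader / writer
# --------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_tsv(path: Path, names: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


def read_mtx_bundle(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    gene_annotation_path: str | Path | None = None,
) -> AnnData:
    """Read an MTX bundle into an AnnData (cells x genes, sparse integers).

    Orientation is auto-detected from the MatrixMarket header dimensions
    against the barcode/feature counts; a square matrix defaults to the
    CellRanger genes-as-rows dialect.  An optional gene-annotation TSV
    (gene_id, chromosome, position, mito, housekeeper) is merged into
    ``var``.
    """
    with _open_maybe_gz(Path(matrix_path)) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    barcodes = _read_tsv(Path(barcodes_path), ["barcode"])["barcode"].astype(str)
    feats = _read_tsv(Path(features_path), ["gene_id", "name", "feature_type"])
    n_bar, n_feat = len(barcodes), len(feats)

    if mat.shape == (n_feat, n_bar):
        mat = mat.T.tocsr()
    elif mat.shape != (n_bar, n_feat):
        raise FormatError(
            f"matrix shape {mat.shape} matches neither (cells={n_bar}, "
            f"genes={n_feat}) nor its transpose"
        )
    if barcodes.duplicated().any():
        dups = barcodes[barcodes.duplicated()].tolist()
        raise FormatError(f"duplicate barcodes: {dups[:5]}")
    if feats["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in features file")
    data = mat.data
    if data.size and (not np.all(np.isfinite(data)) or np.any(data != np.round(data))
                      or np.any(data < 0)):
        raise FormatError("matrix values must be finite non-negative integers")
    mat = sp.csr_matrix((data.astype(np.int64), mat.indices, mat.indptr), shape=mat.shape)

    var = feats.set_index("gene_id")
    if gene_annotation_path is not None:
        ann = pd.read_csv(gene_annotation_path, sep="\t", index_col=0)
        var = var.join(ann, how="left")
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return AnnData(X=mat, obs=obs, var=var)


def write_mtx_bundle(adata: AnnData, outdir: str | Path, genes_as_rows: bool = True,
                     write_annotation: bool = True) -> dict[str, Path]:
    """Write an AnnData as matrix.mtx / barcodes.tsv / features.tsv
    (+ genes.tsv annotation sidecar when gene metadata is present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    if genes_as_rows:
        X = X.T
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], X, field="integer")
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t",
                                      header=False, index=False)
    feature_type = adata.var.get(
        "feature_type", pd.Series("Gene Expression", index=adata.var_names)
    )
    name = adata.var.get("name", pd.Series(adata.var_names, index=adata.var_names))
    pd.DataFrame({
        "gene_id": adata.var_names, "name": np.asarray(name),
        "feature_type": np.asarray(feature_type),
    }).to_csv(paths["features"], sep="\t", header=False, index=False)
    ann_cols = [c for c in ("chromosome", "position", "mito", "housekeeper", "program")
                if c in adata.var.columns]
    if write_annotation and ann_cols:
        paths["annotation"] = outdir / "genes.tsv"
        adata.var[ann_cols].to_csv(paths["annotation"], sep="\t")
    return paths


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

def compute_cell_qc(adata: AnnData, housekeeper_set: list[str] | None = None) -> pd.DataFrame:
    """Per-cell QC table: total_umis, n_genes_detected, mito_fraction,
    n_housekeepers_detected.  Detection means count > 0; mito_fraction is 0
    for all-zero cells.  The housekeeper set defaults to the
    ``housekeeper`` flag in ``var``."""
    X = sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    if "mito" in adata.var.columns:
        mito_mask = adata.var["mito"].to_numpy().astype(bool)
    else:
        mito_mask = np.zeros(adata.n_vars, dtype=bool)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    if housekeeper_set is None:
        hk_mask = (adata.var["housekeeper"].to_numpy().astype(bool)
                   if "housekeeper" in adata.var.columns
                   else np.zeros(adata.n_vars, dtype=bool))
    else:
        hk_mask = adata.var_names.isin(housekeeper_set)
        if not hk_mask.any() and len(housekeeper_set) > 0:
            warnings.warn("housekeeper set shares no genes with the matrix; "
                          "housekeeper counts will all be 0")
    n_hk = (X[:, hk_mask] > 0).sum(axis=1)
    n_hk = np.asarray(n_hk).ravel() if hk_mask.any() else np.zeros(adata.n_obs, dtype=int)
    return pd.DataFrame(
        {
            "total_umis": total.astype(np.int64),
            "n_genes_detected": n_genes.astype(np.int64),
            "mito_fraction": mito_frac,
            "n_housekeepers_detected": np.asarray(n_hk).ravel().astype(np.int64),
        },
        index=adata.obs_names.copy(),
    )


def filter_cells(
    adata: AnnData,
    profile: QCProfile = QC_PROFILES["default"],
    housekeeper_set: list[str] | None = None,
) -> tuple[AnnData, pd.DataFrame]:
    """Apply the strict-threshold cell-calling predicate.

    Returns the filtered matrix and a per-cell report with the QC metrics,
    per-criterion pass flags and a ``failed`` column naming the criteria a
    cell failed (empty string for passing cells)."""
    qc = compute_cell_qc(adata, housekeeper_set=housekeeper_set)
    report = qc.copy()
    checks = {}
    if profile.min_umis is not None:
        checks["umis"] = qc["total_umis"] > profile.min_umis
    checks["mito"] = qc["mito_fraction"] < profile.max_mito_fraction
    if profile.min_housekeepers is not None:
        checks["housekeepers"] = qc["n_housekeepers_detected"] > profile.min_housekeepers
    if profile.min_genes is not None:
        checks["genes"] = qc["n_genes_detected"] > profile.min_genes
    passed = np.ones(adata.n_obs, dtype=bool)
    for name, ok in checks.items():
        report[f"pass_{name}"] = ok.to_numpy()
        passed &= ok.to_numpy()
    report["pass"] = passed
    report["failed"] = [
        ",".join(n for n, ok in checks.items() if not ok.iloc[i]) for i in range(adata.n_obs)
    ]
    filtered = adata[passed].copy()
    if filtered.n_obs == 0:
        warnings.warn("no cells passed QC")
    return filtered, report


# --------------------------------------------------------------------------
# HTO demultiplexing
# --------------------------------------------------------------------------

def demultiplex_hto(hto: AnnData, thresholds: dict[str, float]) -> pd.DataFrame:
    """Classify each cell from its HTO counts with per-hashtag manual
    thresholds: the positive set is every HTO with count >= its threshold;
    one positive -> singlet (assigned that HTO), two or more -> doublet,
    none -> negative."""
    missing = [h for h in hto.var_names if h not in thresholds]
    if missing:
        raise ConfigurationError(f"no threshold configured for HTO(s): {missing}")
    thr = np.array([thresholds[h] for h in hto.var_names], dtype=float)
    if np.any(thr <= 0):
        raise ConfigurationError("HTO thresholds must be positive")
    X = np.asarray(hto.X.todense()) if sp.issparse(hto.X) else np.asarray(hto.X)
    positive = X >= thr[None, :]
    n_pos = positive.sum(axis=1)
    call = np.where(n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet"))
    first_pos = positive.argmax(axis=1)
    hto_id = np.where(n_pos == 1, np.asarray(hto.var_names)[first_pos], None)
    return pd.DataFrame(
        {"call": call, "hto": hto_id, "n_positive": n_pos},
        index=hto.obs_names.copy(),
    )


def suggest_hto_thresholds(hto: AnnData) -> dict[str, float]:
    """Suggest per-HTO thresholds at the midpoint (in log space) between a
    two-component split of the log1p counts.  A helper only — thresholds
    are always explicit configuration and never applied silently."""
    X = np.asarray(hto.X.todense()) if sp.issparse(hto.X) else np.asarray(hto.X)
    out = {}
    for j, h in enumerate(hto.var_names):
        v = np.log1p(X[:, j].astype(float))
        lo, hi = v.min(), v.max()
        if hi - lo < 1e-12:
            out[h] = float(np.expm1(hi)) + 1.0
            continue
        # 1-D two-means split
        c0, c1 = lo, hi
        for _ in range(50):
            mid = (c0 + c1) / 2
            g0, g1 = v[v <= mid], v[v > mid]
            n0 = g0.mean() if g0.size else c0
            n1 = g1.mean() if g1.size else c1
            if abs(n0 - c0) < 1e-9 and abs(n1 - c1) < 1e-9:
                break
            c0, c1 = n0, n1
        out[h] = float(np.expm1((c0 + c1) / 2))
    return out


def remove_doublets(
    adata: AnnData, assignment: pd.DataFrame, keep_negatives: bool = False
) -> AnnData:
    """Drop cells called doublet (and, by default, negatives) and annotate
    singlets with the sample of origin from their HTO."""
    assignment = assignment.reindex(adata.obs_names)
    if assignment["call"].isna().any():
        raise ConfigurationError("assignment does not cover all barcodes")
    keep = assignment["call"] != "doublet"
    if not keep_negatives:
        keep &= assignment["call"] != "negative"
    out = adata[keep.to_numpy()].copy()
    singlet = assignment.loc[out.obs_names, "call"] == "singlet"
    out.obs.loc[singlet, "sample"] = assignment.loc[out.obs_names, "hto"][singlet]
    return out
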