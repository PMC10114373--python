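"""Log-normalization, cluster fold changes and program scoring.

Normalization follows the standard single-cell convention: counts are
scaled per cell to a fixed total (default 10,000) and natural-log1p
transformed.  Differential expression between a cluster and its comparison
universe is reported as the log2 fold change of de-normalized group means
with a pseudocount, together with the fraction of cells expressing each
gene on either side; no p-values are computed because downstream stages
consume fold changes and percentage filters only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import ValidationError


def log_normalize(adata: AnnData, scale_factor: float = 10_000.0) -> AnnData:
    """Return a new AnnData with ``X = ln(1 + count / cell_total * scale_factor)``
    and the raw counts preserved in ``layers['counts']``.

    Zeros stay exactly zero.  All-zero cells are an error (QC runs first)
    and are reported by barcode.
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = list(adata.obs_names[totals == 0][:10])
        raise ValidationError(f"all-zero cells present (run QC first): {bad}")
    norm = X.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    out.layers["counts"] = sp.csr_matrix(adata.X).copy()
    out.uns = dict(adata.uns)
    out.uns["scale_factor"] = float(scale_factor)
    return out


@dataclass
class ClusterProfile:
    """Per-gene differential expression of one cluster against its
    comparison universe: log2 fold change of de-normalized means and the
    fraction of expressing cells on each side."""

    cluster: str
    table: pd.DataFrame  # index: gene_id; columns: log2fc, pct_in, pct_out
    n_cluster: int
    n_other: int
    patient: str | None = None
    params: dict = field(default_factory=dict)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


def _group_indices(adata: AnnData, cells) -> np.ndarray:
    pos = pd.Index(adata.obs_names).get_indexer(pd.Index(cells))
    if (pos < 0).any():
        missing = list(pd.Index(cells)[pos < 0][:5])
        raise ValidationError(f"cells not in matrix: {missing}")
    return pos


def cluster_log2fc(
    norm: AnnData,
    cluster_cells,
    other_cells,
    pseudocount: float = 1.0,
    detection_min_umis: int = 1,
    cluster_name: str = "cluster",
) -> ClusterProfile:
    """log2 fold change of the cluster against the other cells.

    ``log2fc(g) = log2(mean_in(expm1 value) + pc) - log2(mean_out(expm1
    value) + pc)``; pct_in / pct_out count cells with
    ``count >= detection_min_umis``.  Cluster and comparison sets must be
    disjoint and non-empty.
    """
    ci = _group_indices(norm, cluster_cells)
    oi = _group_indices(norm, other_cells)
    if len(ci) == 0 or len(oi) == 0:
        raise ValidationError("cluster and comparison sets must be non-empty")
    if np.intersect1d(ci, oi).size:
        raise ValidationError("cluster and comparison sets overlap")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    X = sp.csr_matrix(norm.X)
    expm1 = X.copy()
    expm1.data = np.expm1(expm1.data)
    mean_in = np.asarray(expm1[ci].mean(axis=0)).ravel()
    mean_out = np.asarray(expm1[oi].mean(axis=0)).ravel()
    log2fc = np.log2(mean_in + pseudocount) - np.log2(mean_out + pseudocount)

    counts = sp.csr_matrix(norm.layers["counts"]) if "counts" in norm.layers else X
    det = counts >= detection_min_umis
    pct_in = np.asarray(det[ci].mean(axis=0)).ravel()
    pct_out = np.asarray(det[oi].mean(axis=0)).ravel()
    table = pd.DataFrame(
        {"log2fc": log2fc, "pct_in": pct_in, "pct_out": pct_out},
        index=norm.var_names.copy(),
    )
    return ClusterProfile(
        cluster=cluster_name, table=table, n_cluster=len(ci), n_other=len(oi),
        params={"pseudocount": pseudocount, "detection_min_umis": detection_min_umis},
    )


def filter_de_genes(
    profile: ClusterProfile, min_log2fc: float = 0.25, min_pct: float = 0.10
) -> list[str]:
    """Genes with log2 fold change strictly greater than ``min_log2fc`` and
    at least ``min_pct`` expressing cells within the cluster *or* the
    comparison universe (i.e. max of the two sides)."""
    t = profile.table
    keep = (t["log2fc"] > min_log2fc) & (
        np.maximum(t["pct_in"], t["pct_out"]) >= min_pct
    )
    return list(t.index[keep])


def score_program(
    norm: AnnData,
    program_genes,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-controlled program score per cell.

    All genes are ranked by mean expression into ``n_bins`` equal-size
    bins; for each program gene, ``n_ctrl`` control genes are sampled from
    its bin; the score is the mean program expression minus the mean
    control expression.  Program genes missing from the matrix are dropped
    with a warning; an empty program after intersection is an error.
    Deterministic given ``seed``.
    """
    genes = pd.Index(program_genes)
    present = genes[genes.isin(norm.var_names)]
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} program genes absent from matrix"
        )
    if len(present) == 0:
        raise ValidationError("program has no genes in the matrix")
    X = sp.csr_matrix(norm.X)
    gene_mean = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(norm.n_vars, dtype=int)
    bin_of[order] = np.arange(norm.n_vars) * n_bins // norm.n_vars
    bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]

    rng = np.random.default_rng(seed)
    prog_idx = pd.Index(norm.var_names).get_indexer(present)
    ctrl_idx = np.concatenate([
        rng.choice(bins[bin_of[g]], size=n_ctrl, replace=True) for g in prog_idx
    ])
    prog_mean = np.asarray(X[:, prog_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(prog_mean - ctrl_mean, index=norm.obs_names.copy(), name="score")


def score_signature_mean(norm: AnnData, signature_genes) -> pd.Series:
    """Mean log-normalized expression of the signature genes per cell."""
    genes = pd.Index(signature_genes)
    present = genes[genes.isin(norm.var_names)]
    if len(present) == 0:
        raise ValidationError("signature has no genes in the matrix")
    X = sp.csr_matrix(norm.X)
    idx = pd.Index(norm.var_names).get_indexer(present)
    return pd.Series(
        np.asarray(X[:, idx].mean(axis=1)).ravel(),
        index=norm.obs_names.copy(),
        name="score",
    )


def assign_phase(s_score, g2m_score):
    """Cell-cycle phase from S and G2M program scores: G1 when both are
    non-positive, otherwise the phase of the larger score (ties toward
    G2M)."""
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    phase = np.where((s <= 0) & (g <= 0), "G1", np.where(s > g, "S", "G2M"))
    if phase.ndim == 0:
        return str(phase)
    if isinstance(s_score, pd.Series):
        return pd.Series(phase, index=s_score.index, name="phase")
    return phase
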