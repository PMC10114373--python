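"""Signature-matrix construction and bulk deconvolution by NNLS.

A cell-type signature matrix is built from labelled single-cell counts:
phenotypes named for subsampling (by default 75% of T and B cells, which
otherwise dominate the fit) are down-sampled with a seed, genes detected
in fewer than 5% of cells in *every* phenotype are removed, and each
phenotype's mean count profile is scaled to counts-per-million.  Bulk
profiles are CPM-normalized and deconvolved by non-negative least squares
on the shared-gene intersection; estimated fractions are renormalized to a
probability vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from anndata import AnnData

from .errors import ValidationError

DEFAULT_SUBSAMPLE = {"T cells": 0.75, "B cells": 0.75}


@dataclass
class SignatureMatrix:
    """Genes x cell-types mean expression on CPM scale, with the gene
    filter and subsampling provenance."""

    values: pd.DataFrame
    min_pct: float
    filter_scope: str
    subsample: dict[str, float]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


def build_signature_matrix(
    adata: AnnData,
    labels: pd.Series,
    min_pct: float = 0.05,
    subsample: dict[str, float] | None = None,
    seed: int = 0,
    filter_scope: str = "all",
    min_cells: int = 10,
) -> SignatureMatrix:
    """Build the signature matrix from labelled single-cell counts.

    ``filter_scope='all'`` removes a gene only when its detection fraction
    is below ``min_pct`` in every phenotype (keeps phenotype-specific
    markers); ``'any'`` removes it when below in any phenotype.
    Deterministic given ``seed``.
    """
    if subsample is None:
        subsample = dict(DEFAULT_SUBSAMPLE)
    if filter_scope not in ("all", "any"):
        raise ValidationError("filter_scope must be 'all' or 'any'")
    labels = labels.reindex(adata.obs_names).dropna()
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValidationError("need at least 2 phenotypes")
    counts_by_type = labels.value_counts()
    small = [t for t in types if counts_by_type[t] < min_cells]
    if small:
        raise ValidationError(f"phenotypes below {min_cells} cells: {small}")

    rng = np.random.default_rng(seed)
    keep_cells: list[str] = []
    realized_subsample = {}
    for t in types:
        cells = list(labels.index[labels == t])
        frac = subsample.get(t)
        if frac is not None:
            n_keep = int(round(len(cells) * frac))
            picked = rng.choice(len(cells), size=n_keep, replace=False)
            cells = [cells[i] for i in sorted(picked)]
            realized_subsample[t] = frac
        keep_cells.extend(cells)
    sub = adata[keep_cells]
    sub_labels = labels.loc[keep_cells]

    X = sp.csr_matrix(sub.X, dtype=np.float64)
    det_frac = {}
    mean_prof = {}
    for t in types:
        mask = (sub_labels == t).to_numpy()
        block = X[mask]
        det_frac[t] = np.asarray((block > 0).mean(axis=0)).ravel()
        mean_prof[t] = np.asarray(block.mean(axis=0)).ravel()
    det = np.vstack([det_frac[t] for t in types])
    below = det < min_pct
    removed = below.all(axis=0) if filter_scope == "all" else below.any(axis=0)
    keep_genes = ~removed

    prof = np.vstack([mean_prof[t] for t in types]).T[keep_genes]
    col_sums = prof.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValidationError("a phenotype has zero total expression after filtering")
    values = pd.DataFrame(
        prof / col_sums[None, :] * 1e6,
        index=adata.var_names[keep_genes].copy(),
        columns=types,
    )
    all_zero = (values.sum(axis=1) == 0)
    values = values.loc[~all_zero]
    return SignatureMatrix(
        values=values, min_pct=min_pct, filter_scope=filter_scope,
        subsample=realized_subsample, seed=seed,
        params={"n_cells_used": len(keep_cells), "n_genes_removed": int(removed.sum())},
    )


def cpm_normalize(bulk: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per column: value / column-sum * 1e6."""
    sums = bulk.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"zero column sum in sample(s): {list(zero.index)}")
    return bulk / sums * 1e6


@dataclass
class MixtureEstimate:
    """Per-sample cell-type fractions (non-negative, summing to 1) and the
    NNLS residual norm on CPM scale."""

    fractions: pd.DataFrame  # samples x cell types
    residuals: pd.Series
    n_shared_genes: int

    def __post_init__(self):
        sums = self.fractions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


def deconvolve_nnls(bulk_cpm: pd.DataFrame, signature: SignatureMatrix) -> MixtureEstimate:
    """Deconvolve CPM bulk profiles against the signature matrix.

    Solves min ||S f - b||^2, f >= 0 per sample on the shared-gene
    intersection and reports f / sum(f); an all-zero solution falls back
    to uniform fractions with a warning.
    """
    shared = bulk_cpm.index.intersection(signature.values.index)
    types = signature.cell_types
    if len(shared) < len(types):
        raise ValidationError(
            f"only {len(shared)} shared genes for {len(types)} cell types"
        )
    S = signature.values.loc[shared].to_numpy()
    fracs, resid = {}, {}
    for sample in bulk_cpm.columns:
        b = bulk_cpm.loc[shared, sample].to_numpy(dtype=float)
        f, r = scipy.optimize.nnls(S, b)
        total = f.sum()
        if total == 0:
            warnings.warn(f"{sample}: NNLS returned all-zero; uniform fractions")
            f = np.full(len(types), 1.0 / len(types))
        else:
            f = f / total
        fracs[sample] = f
        resid[sample] = float(r)
    return MixtureEstimate(
        fractions=pd.DataFrame(fracs, index=types).T,
        residuals=pd.Series(resid, name="residual_norm"),
        n_shared_genes=len(shared),
    )
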