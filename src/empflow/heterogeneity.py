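"""Cross-patient heterogeneity comparison and EMP signature derivation.

Intratumoral heterogeneity is compared across patients by computing, for
every (patient, cluster), the *unfiltered* log2 fold-change vector of that
cluster against all other tumor cells of the same patient, then taking
uncentered cosine similarities between these vectors on a shared gene
universe.  Epithelial / partial-EMT gene signatures are derived from the
fold changes between the epithelial and pEMT clusters with strict
|log2FC| > 1 and a 10% expressing-fraction rule.  Heatmap row/column
ordering uses Ward-D2 hierarchical clustering on Euclidean or Spearman
correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from anndata import AnnData

from .errors import ValidationError
from .normalize import ClusterProfile, cluster_log2fc


def patient_cluster_profiles(
    norm: AnnData,
    labels: pd.DataFrame,
    min_cells: int = 50,
    pseudocount: float = 1.0,
) -> list[ClusterProfile]:
    """One unfiltered fold-change profile per (patient, cluster).

    ``labels`` has one row per cell (indexed by barcode) with ``patient``
    and ``cluster`` columns; the comparison universe of each cluster is all
    other labelled cells of the same patient.  Patients with at most
    ``min_cells`` cells (strict: more than ``min_cells`` required) or with
    a single cluster are skipped with a warning.
    """
    labels = labels.reindex(norm.obs_names).dropna(subset=["patient", "cluster"])
    profiles: list[ClusterProfile] = []
    for patient, sub in labels.groupby("patient", sort=True):
        if len(sub) <= min_cells:
            warnings.warn(f"{patient}: {len(sub)} cells <= {min_cells}, excluded")
            continue
        clusters = sorted(sub["cluster"].unique())
        if len(clusters) < 2:
            warnings.warn(f"{patient}: single cluster, skipped")
            continue
        for cl in clusters:
            in_cells = sub.index[sub["cluster"] == cl]
            out_cells = sub.index[sub["cluster"] != cl]
            prof = cluster_log2fc(
                norm, in_cells, out_cells, pseudocount=pseudocount,
                cluster_name=str(cl),
            )
            prof.patient = str(patient)
            profiles.append(prof)
    return profiles


def cosine_similarity_matrix(
    profiles: list[ClusterProfile], universe: str = "intersection"
) -> pd.DataFrame:
    """Pairwise uncentered cosine similarity between fold-change vectors.

    ``universe`` is the gene-alignment policy: ``intersection`` (genes
    present in every profile) or ``union`` (missing genes zero-filled).
    Zero-norm vectors get similarity 0 with a warning.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles")
    gene_sets = [p.table.index for p in profiles]
    if universe == "intersection":
        shared = gene_sets[0]
        for g in gene_sets[1:]:
            shared = shared.intersection(g)
    elif universe == "union":
        shared = gene_sets[0]
        for g in gene_sets[1:]:
            shared = shared.union(g)
    else:
        raise ValidationError(f"unknown universe policy {universe!r}")
    if len(shared) == 0:
        raise ValidationError("empty shared gene universe")
    shared = shared.sort_values()

    ids = []
    vecs = []
    for p in profiles:
        ids.append(f"{p.patient}:{p.cluster}" if p.patient else p.cluster)
        vecs.append(p.table["log2fc"].reindex(shared).fillna(0.0).to_numpy())
    V = np.vstack(vecs)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        warnings.warn("zero-norm fold-change vector(s); similarity set to 0")
    safe = np.where(norms == 0, 1.0, norms)
    sim = (V @ V.T) / np.outer(safe, safe)
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, np.where(norms == 0, 0.0, 1.0))
    return pd.DataFrame(sim, index=ids, columns=ids)


@dataclass
class SignaturePair:
    """Disjoint epithelial-differentiation and partial-EMT gene lists with
    the thresholds used to derive them."""

    epithelial: list[str]
    pemt: list[str]
    min_abs_log2fc: float
    min_pct: float

    def __post_init__(self):
        if set(self.epithelial) & set(self.pemt):
            raise ValidationError("signature lists must be disjoint")


def derive_emp_signatures(
    epi_vs_pemt: ClusterProfile,
    min_abs_log2fc: float = 1.0,
    min_pct: float = 0.10,
) -> SignaturePair:
    """Derive the epithelial and pEMT signatures from the epithelial-vs-pEMT
    fold-change profile: genes with log2FC strictly above ``min_abs_log2fc``
    go to the epithelial list, strictly below the negative to the pEMT
    list; both require at least ``min_pct`` expressing cells on either
    side.  Empty lists warn but do not fail."""
    t = epi_vs_pemt.table
    pct_ok = np.maximum(t["pct_in"], t["pct_out"]) >= min_pct
    epi = list(t.index[(t["log2fc"] > min_abs_log2fc) & pct_ok])
    pemt = list(t.index[(t["log2fc"] < -min_abs_log2fc) & pct_ok])
    if not epi or not pemt:
        warnings.warn("one or both derived signatures are empty")
    return SignaturePair(epithelial=epi, pemt=pemt,
                         min_abs_log2fc=min_abs_log2fc, min_pct=min_pct)


def ward_order(
    matrix: pd.DataFrame, distance: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Ward-D2 hierarchical clustering of the rows for heatmap ordering.

    ``distance`` is ``euclidean`` or ``spearman`` (1 - Spearman correlation
    between rows).  Rows are pre-sorted by id so tie-breaking is
    deterministic.  Returns (ordered row ids, scipy linkage matrix).
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need at least 2 items to cluster")
    matrix = matrix.loc[sorted(matrix.index)]
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in clustering input")
    if distance == "euclidean":
        d = ssd.pdist(X, metric="euclidean")
    elif distance == "spearman":
        ranks = pd.DataFrame(X.T).rank().to_numpy()
        corr = np.corrcoef(ranks.T)
        d = ssd.squareform(1.0 - corr, checks=False)
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite distances")
    Z = sch.linkage(d, method="ward")
    leaves = sch.leaves_list(Z)
    return [matrix.index[i] for i in leaves], Z


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string (branch lengths are
    merge heights) for plain-text export."""
    tree = sch.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

    return walk(tree) + ";"
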