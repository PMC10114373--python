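"""Log-normalization, fold-change arithmetic, program scoring, phases."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from hypothesis import given, settings, strategies as st

import empflow as ef
from empflow.errors import ValidationError
from conftest import make_norm


class TestLogNormalize:
    def test_zero_counts_stay_zero_and_closed_form(self):
        X = sp.csr_matrix(np.array([[1, 0, 9999]], dtype=np.int64))
        adata = AnnData(X=X, obs=pd.DataFrame(index=["c"]),
                        var=pd.DataFrame(index=["a", "b", "c"]))
        norm = ef.log_normalize(adata, scale_factor=10_000)
        v = np.asarray(norm.X.todense()).ravel()
        # cell total 10,000 and count 1 -> ln(1 + 1) = ln 2
        assert v[0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert v[1] == 0.0

    def test_matches_dense_bruteforce_and_scanpy(self, cohort):
        _, adata, _ = cohort
        sub = adata[:50].copy()
        norm = ef.log_normalize(sub)
        dense = np.asarray(sub.X.todense(), dtype=float)
        totals = dense.sum(axis=1, keepdims=True)
        expect = np.log1p(dense / totals * 10_000)
        np.testing.assert_allclose(np.asarray(norm.X.todense()), expect, atol=1e-12)
        # independent route through scanpy
        import scanpy as sc
        ref = sub.copy()
        sc.pp.normalize_total(ref, target_sum=10_000)
        sc.pp.log1p(ref)
        np.testing.assert_allclose(
            np.asarray(norm.X.todense()), np.asarray(ref.X.todense()), atol=1e-9
        )

    def test_all_zero_cell_reported_by_barcode(self):
        X = sp.csr_matrix(np.array([[1, 1], [0, 0]], dtype=np.int64))
        adata = AnnData(X=X, obs=pd.DataFrame(index=["ok", "empty"]),
                        var=pd.DataFrame(index=["a", "b"]))
        with pytest.raises(ValidationError, match="empty"):
            ef.log_normalize(adata)

    def test_monotone_within_cell(self, cohort_norm):
        row = np.asarray(cohort_norm.X[0].todense()).ravel()
        counts = np.asarray(cohort_norm.layers["counts"][0].todense()).ravel()
        order = np.argsort(counts)
        assert np.all(np.diff(row[order]) >= -1e-15)


class TestClusterLog2FC:
    def test_antisymmetry_under_swap(self, cohort_norm, cohort):
        _, _, truth = cohort
        a = truth.cells.index[truth.cells["cell_type"] == "tumor-pEMT"][:80]
        b = truth.cells.index[truth.cells["cell_type"] == "tumor-epi"][:80]
        p1 = ef.cluster_log2fc(cohort_norm, a, b)
        p2 = ef.cluster_log2fc(cohort_norm, b, a)
        np.testing.assert_allclose(p1.table["log2fc"], -p2.table["log2fc"], atol=1e-12)
        np.testing.assert_allclose(p1.table["pct_in"], p2.table["pct_out"], atol=0)

    def test_closed_form_with_pseudocount(self):
        # gene expressed only in the cluster with de-normalized mean 1:
        # log2(1 + 1) - log2(0 + 1) = 1
        vals = np.log1p(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0], [0.0, 0.0]]))
        norm = make_norm(vals)
        prof = ef.cluster_log2fc(norm, ["c0", "c1"], ["c2", "c3"])
        assert prof.table.loc["g0", "log2fc"] == pytest.approx(1.0, abs=1e-12)
        assert prof.table.loc["g1", "log2fc"] == 0.0

    def test_rejects_overlap_and_empty(self, cohort_norm):
        cells = list(cohort_norm.obs_names[:10])
        with pytest.raises(ValidationError):
            ef.cluster_log2fc(cohort_norm, cells, cells[5:] + [cohort_norm.obs_names[20]])
        with pytest.raises(ValidationError):
            ef.cluster_log2fc(cohort_norm, [], cells)

    def test_pct_uses_detection_threshold(self):
        counts = np.array([[0, 1], [1, 2], [2, 5], [5, 0]])
        vals = np.log1p(counts.astype(float))
        norm = make_norm(vals, counts=counts)
        p1 = ef.cluster_log2fc(norm, ["c0", "c1"], ["c2", "c3"], detection_min_umis=1)
        assert p1.table.loc["g0", "pct_in"] == 0.5
        p2 = ef.cluster_log2fc(norm, ["c0", "c1"], ["c2", "c3"], detection_min_umis=2)
        assert p2.table.loc["g0", "pct_in"] == 0.0
        assert p2.table.loc["g0", "pct_out"] == 1.0


class TestFilterDEGenes:
    def _profile(self, log2fc, pct_in, pct_out):
        table = pd.DataFrame({
            "log2fc": log2fc, "pct_in": pct_in, "pct_out": pct_out,
        }, index=[f"g{i}" for i in range(len(log2fc))])
        return ef.ClusterProfile(cluster="x", table=table, n_cluster=1, n_other=1)

    def test_boundary_is_strict_and_pct_is_either_side(self):
        prof = self._profile(
            log2fc=[0.25, 0.26, 0.5, 0.5],
            pct_in=[0.5, 0.5, 0.09, 0.05],
            pct_out=[0.5, 0.5, 0.12, 0.05],
        )
        kept = ef.filter_de_genes(prof)
        assert kept == ["g1", "g2"]  # g0 at exactly 0.25 excluded; g3 fails pct

    def test_matches_bruteforce_predicate(self):
        rng = np.random.default_rng(4)
        fc = rng.normal(0, 1, 500)
        pi = rng.uniform(0, 1, 500)
        po = rng.uniform(0, 1, 500)
        prof = self._profile(fc, pi, po)
        kept = set(ef.filter_de_genes(prof, 0.25, 0.10))
        expect = {f"g{i}" for i in range(500)
                  if fc[i] > 0.25 and max(pi[i], po[i]) >= 0.10}
        assert kept == expect

    @settings(max_examples=20, deadline=None)
    @given(fc=st.floats(0, 2), pct=st.floats(0, 1))
    def test_output_shrinks_as_thresholds_rise(self, fc, pct):
        rng = np.random.default_rng(9)
        prof = self._profile(rng.normal(0, 1, 300), rng.uniform(0, 1, 300),
                             rng.uniform(0, 1, 300))
        base = set(ef.filter_de_genes(prof, fc, pct))
        tighter = set(ef.filter_de_genes(prof, fc + 0.1, min(1.0, pct + 0.1)))
        assert tighter <= base


class TestProgramScore:
    def test_null_program_scores_near_zero(self, cohort_norm):
        genes = list(cohort_norm.var_names[::40])[:30]
        score = ef.score_program(cohort_norm, genes, seed=0)
        assert abs(score.mean()) < 0.05

    def test_determinism_and_upregulated_subset_detected(self, null_cohort):
        _, adata, truth = null_cohort
        # implant a 2x upregulation of 30 genes in half the cells
        X = np.asarray(adata.X.todense(), dtype=float)
        idx = np.arange(100, 130)
        up_cells = np.arange(adata.n_obs // 2)
        X[np.ix_(up_cells, idx)] *= 2
        mod = AnnData(X=sp.csr_matrix(X), obs=adata.obs.copy(), var=adata.var.copy())
        norm = ef.log_normalize(mod)
        genes = list(adata.var_names[idx])
        s1 = ef.score_program(norm, genes, seed=3)
        s2 = ef.score_program(norm, genes, seed=3)
        pd.testing.assert_series_equal(s1, s2)
        assert s1.iloc[:len(up_cells)].mean() > s1.iloc[len(up_cells):].mean()

    def test_empty_program_is_error(self, cohort_norm):
        with pytest.raises(ValidationError):
            ef.score_program(cohort_norm, ["nope1", "nope2"], seed=0)


class TestSignatureAndPhase:
    def test_single_gene_signature_is_identity(self, cohort_norm):
        g = cohort_norm.var_names[5]
        score = ef.score_signature_mean(cohort_norm, [g])
        col = np.asarray(cohort_norm.X[:, 5].todense()).ravel()
        np.testing.assert_allclose(score.to_numpy(), col, atol=1e-12)

    def test_program_cells_score_higher_on_own_signature(self, cohort, cohort_norm):
        """Cells carrying the epithelial program outscore pEMT cells on the
        epithelial signature (rank-sum p < 0.01)."""
        import scipy.stats
        _, _, truth = cohort
        epi_genes = truth.genes.index[truth.genes["program"] == "epi"]
        score = ef.score_signature_mean(cohort_norm, epi_genes)
        epi = score[truth.cells["cell_type"] == "tumor-epi"]
        pemt = score[truth.cells["cell_type"] == "tumor-pEMT"]
        stat, p = scipy.stats.ranksums(epi, pemt)
        assert stat > 0 and p < 0.01

    @pytest.mark.parametrize("s,g2m,expect", [
        (-0.1, -0.2, "G1"),
        (0.0, 0.0, "G1"),
        (0.5, 0.1, "S"),
        (0.1, 0.5, "G2M"),
        (0.3, 0.3, "G2M"),  # tie toward G2M
        (-0.1, 0.2, "G2M"),
    ])
    def test_phase_assignment(self, s, g2m, expect):
        assert ef.assign_phase(s, g2m) == expect
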