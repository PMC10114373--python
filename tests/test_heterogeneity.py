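"""Cosine similarity, EMP signature derivation, Ward-D2 ordering."""

import numpy as np
import pandas as pd
import pytest

import empflow as ef
from empflow.errors import ValidationError
from empflow.heterogeneity import dendrogram_newick
from conftest import make_norm


def _profile(log2fc, pct_in=None, pct_out=None, cluster="x", patient=None):
    n = len(log2fc)
    table = pd.DataFrame({
        "log2fc": np.asarray(log2fc, dtype=float),
        "pct_in": pct_in if pct_in is not None else np.full(n, 0.5),
        "pct_out": pct_out if pct_out is not None else np.full(n, 0.5),
    }, index=[f"g{i}" for i in range(n)])
    return ef.ClusterProfile(cluster=cluster, table=table, n_cluster=10,
                             n_other=10, patient=patient)


class TestPatientClusterProfiles:
    def test_two_cluster_profiles_negate(self, cohort, cohort_norm):
        _, _, truth = cohort
        tumor = truth.cells[truth.cells["emp_state"].isin(["pEMT", "epi"])]
        labels = pd.DataFrame({
            "patient": tumor["patient"], "cluster": tumor["emp_state"],
        }, index=tumor.index)
        one = labels[labels["patient"] == "patient1"]
        profiles = ef.patient_cluster_profiles(cohort_norm, one)
        assert len(profiles) == 2
        np.testing.assert_allclose(
            profiles[0].table["log2fc"], -profiles[1].table["log2fc"], atol=1e-12
        )

    def test_small_patients_excluded_strictly(self, cohort, cohort_norm):
        """A patient with exactly min_cells tumor cells is excluded (the cut
        is 'more than', strict); one more cell is included."""
        _, _, truth = cohort
        tumor = truth.cells[truth.cells["emp_state"].isin(["pEMT", "epi"])]
        labels = pd.DataFrame({
            "patient": tumor["patient"], "cluster": tumor["emp_state"],
        }, index=tumor.index)
        one = labels[labels["patient"] == "patient1"]
        at_cut = one.iloc[:50]
        assert ef.patient_cluster_profiles(cohort_norm, at_cut) == []
        above = one.iloc[:51]
        assert len(ef.patient_cluster_profiles(cohort_norm, above)) == 2

    def test_matches_per_patient_bruteforce(self, cohort, cohort_norm):
        _, _, truth = cohort
        tumor = truth.cells[truth.cells["emp_state"].isin(["pEMT", "epi", "mix"])]
        labels = pd.DataFrame({
            "patient": tumor["patient"], "cluster": tumor["emp_state"],
        }, index=tumor.index)
        profiles = ef.patient_cluster_profiles(cohort_norm, labels)
        assert len(profiles) == 3 * 3
        for prof in profiles:
            sub = labels[labels["patient"] == prof.patient]
            in_cells = sub.index[sub["cluster"] == prof.cluster]
            out_cells = sub.index[sub["cluster"] != prof.cluster]
            expect = ef.cluster_log2fc(cohort_norm, in_cells, out_cells)
            np.testing.assert_allclose(
                prof.table["log2fc"], expect.table["log2fc"], atol=1e-12
            )


class TestCosineSimilarity:
    def test_identity_orthogonality_scale_invariance(self):
        profs = [
            _profile([1, 2, 3], cluster="a"),
            _profile([2, 4, 6], cluster="b"),
            _profile([1, 0, 0], cluster="c"),
            _profile([0, 1, 0], cluster="d"),
        ]
        sim = ef.cosine_similarity_matrix(profs)
        assert sim.loc["a", "a"] == 1.0
        assert sim.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert sim.loc["c", "d"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_bruteforce(self):
        rng = np.random.default_rng(8)
        vecs = rng.normal(0, 1, (6, 200))
        profs = [_profile(v, cluster=f"k{i}") for i, v in enumerate(vecs)]
        sim = ef.cosine_similarity_matrix(profs).to_numpy()
        for i in range(6):
            for j in range(6):
                expect = vecs[i] @ vecs[j] / (
                    np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])
                )
                assert abs(sim[i, j] - expect) < 1e-12
        np.testing.assert_allclose(sim, sim.T, atol=1e-12)
        # independent route: scikit-learn
        from sklearn.metrics.pairwise import cosine_similarity as sk_cos
        np.testing.assert_allclose(sim, sk_cos(vecs), atol=1e-12)

    def test_zero_norm_vector_gets_zero_similarity(self):
        profs = [_profile([0, 0, 0], cluster="z"), _profile([1, 2, 3], cluster="a")]
        sim = ef.cosine_similarity_matrix(profs)
        assert sim.loc["z", "a"] == 0.0 and sim.loc["z", "z"] == 0.0

    def test_within_phenotype_similarity_exceeds_between(self, cohort, cohort_norm):
        """Shared EMP programs across patients: epi clusters of different
        patients are more similar to each other than to pEMT clusters."""
        _, _, truth = cohort
        tumor = truth.cells[truth.cells["emp_state"].isin(["pEMT", "epi"])]
        labels = pd.DataFrame({
            "patient": tumor["patient"], "cluster": tumor["emp_state"],
        }, index=tumor.index)
        profiles = ef.patient_cluster_profiles(cohort_norm, labels)
        sim = ef.cosine_similarity_matrix(profiles)
        ids = list(sim.index)
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if a.split(":")[0] == b.split(":")[0]:
                    continue  # same patient
                (within if a.split(":")[1] == b.split(":")[1] else between).append(
                    sim.loc[a, b]
                )
        assert np.mean(within) > np.mean(between)


class TestSignatureDerivation:
    def test_threshold_rules(self):
        prof = _profile(
            [1.2, 1.0, -1.5, -1.5, 0.5],
            pct_in=[0.15, 0.5, 0.05, 0.05, 0.5],
            pct_out=[0.05, 0.5, 0.09, 0.12, 0.5],
        )
        pair = ef.derive_emp_signatures(prof)
        assert pair.epithelial == ["g0"]      # 1.2 > 1 with pct 0.15
        assert "g1" not in pair.epithelial    # exactly 1.0 excluded (strict)
        assert pair.pemt == ["g3"]            # g2 fails the 10% rule on both sides

    def test_antisymmetry_under_role_swap(self, cohort, cohort_norm):
        _, _, truth = cohort
        epi = truth.cells.index[truth.cells["cell_type"] == "tumor-epi"]
        pemt = truth.cells.index[truth.cells["cell_type"] == "tumor-pEMT"]
        fwd = ef.derive_emp_signatures(ef.cluster_log2fc(cohort_norm, epi, pemt))
        rev = ef.derive_emp_signatures(ef.cluster_log2fc(cohort_norm, pemt, epi))
        assert fwd.epithelial == rev.pemt
        assert fwd.pemt == rev.epithelial

    def test_lists_are_disjoint_by_construction(self):
        with pytest.raises(ValidationError):
            ef.SignaturePair(epithelial=["a"], pemt=["a"],
                             min_abs_log2fc=1, min_pct=0.1)


class TestWardOrder:
    def test_identical_rows_merge_first_at_zero_height(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                         index=["a", "b", "c"])
        order, Z = ef.ward_order(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        # identical rows are adjacent leaves
        ia, ib = order.index("a"), order.index("b")
        assert abs(ia - ib) == 1

    def test_coincident_pair_merges_before_outlier(self):
        m = pd.DataFrame([[0.0], [0.0], [10.0]], index=["p", "q", "far"])
        order, Z = ef.ward_order(m)
        sorted_ids = sorted(m.index)  # rows are id-sorted before clustering
        first_pair = {sorted_ids[int(Z[0, 0])], sorted_ids[int(Z[0, 1])]}
        assert first_pair == {"p", "q"}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_linkage_matches_lance_williams_recursion(self):
        """Ward-D2 heights from a textbook Lance-Williams implementation."""
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (7, 4))
        m = pd.DataFrame(X, index=[f"i{k}" for k in range(7)])
        _, Z = ef.ward_order(m)

        # brute-force agglomeration on squared distances
        import itertools
        clusters = {i: [i] for i in range(7)}
        d2 = {}
        for i, j in itertools.combinations(range(7), 2):
            d2[(i, j)] = np.sum((X[i] - X[j]) ** 2)
        sizes = {i: 1 for i in range(7)}
        heights = []
        next_id = 7
        while len(clusters) > 1:
            (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
            heights.append(np.sqrt(best))
            for other in list(clusters):
                if other in (a, b):
                    continue
                key_a = tuple(sorted((a, other)))
                key_b = tuple(sorted((b, other)))
                na, nb, no = sizes[a], sizes[b], sizes[other]
                merged = ((na + no) * d2[key_a] + (nb + no) * d2[key_b]
                          - no * best) / (na + nb + no)
                d2[tuple(sorted((next_id, other)))] = merged
            for other in list(clusters):
                d2.pop(tuple(sorted((a, other))), None)
                d2.pop(tuple(sorted((b, other))), None)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            sizes[next_id] = sizes.pop(a) + sizes.pop(b)
            next_id += 1
        np.testing.assert_allclose(Z[:, 2], heights, atol=1e-9)

    def test_spearman_distance_mode_runs(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(0, 1, (5, 30)), index=list("abcde"))
        order, Z = ef.ward_order(m, distance="spearman")
        assert sorted(order) == list("abcde")
        nwk = dendrogram_newick(Z, sorted(m.index))
        assert nwk.endswith(";") and "a" in nwk

    def test_nonfinite_rejected(self):
        m = pd.DataFrame([[np.nan, 1.0], [0.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValidationError):
            ef.ward_order(m)
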