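"""Reference building, concordance filtering and weighted-NNLS deconvolution."""

import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from adipomr import synthetic
from adipomr.deconvolution import (
    DeconvolutionError,
    ReferenceProfiles,
    adjust_proportions,
    build_pseudobulk,
    concordance_filter,
    deconvolve_samples,
    loo_validate,
    qc_reference,
    select_signature_genes,
    true_proportions,
    wnnls_deconvolve,
)
from adipomr.expression import residualize


def _adata(X, subjects, clusters):
    X = np.asarray(X, dtype=np.int32)
    obs = pd.DataFrame(
        {"subject": subjects, "cluster": clusters},
        index=[f"c{i}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])])
    return AnnData(X=X, obs=obs, var=var)


class TestQC:
    def test_boundary_cell_with_299_genes_removed(self):
        n_genes = 400
        X = np.ones((3, n_genes), dtype=int)
        X[1, 299:] = 0  # cell 1 expresses exactly 299 genes
        ad = _adata(X, ["s1"] * 3, ["t1"] * 3)
        out, report = qc_reference(ad, min_genes=300, min_cells=1)
        assert report["cells_removed"] == 1
        assert "c1" not in out.obs_names

    def test_gene_boundary_three_vs_two_cells(self):
        X = np.ones((4, 320), dtype=int)
        X[0, 0] = 0  # gene 0 expressed in 3 cells -> kept
        X[:2, 1] = 0  # gene 1 expressed in 2 cells -> dropped
        ad = _adata(X, ["s1"] * 4, ["t1"] * 4)
        out, _ = qc_reference(ad, min_genes=300, min_cells=3)
        assert "g0" in out.var_names and "g1" not in out.var_names

    def test_no_removal_when_all_pass(self):
        X = np.ones((5, 500), dtype=int)
        ad = _adata(X, ["s1"] * 5, ["t1"] * 5)
        out, report = qc_reference(ad)
        assert report["cells_removed"] == 0 and report["genes_removed"] == 0

    def test_everything_removed_errors(self):
        X = np.zeros((3, 350), dtype=int)
        X[:, 0] = 1
        ad = _adata(X, ["s1"] * 3, ["t1"] * 3)
        with pytest.raises(DeconvolutionError):
            qc_reference(ad)


class TestTrueProportions:
    def test_counting_fixture(self):
        meta = pd.DataFrame(
            {"subject": ["s1"] * 10,
             "cluster": ["a"] * 7 + ["b"] * 2 + ["c"]}
        )
        props = true_proportions(meta)
        np.testing.assert_allclose(props.loc["s1", ["a", "b", "c"]], [0.7, 0.2, 0.1])

    def test_single_type_is_one(self):
        meta = pd.DataFrame({"subject": ["s1"] * 5, "cluster": ["a"] * 5})
        assert true_proportions(meta).loc["s1", "a"] == 1.0

    def test_rows_sum_to_one(self, small_reference):
        _, _, qcd, _ = small_reference
        props = true_proportions(qcd.obs)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)


class TestSignatureGenes:
    def test_recovers_true_markers_in_strong_regime(self):
        cfg = synthetic.CellSimConfig(
            n_subjects=4, n_celltypes=4, n_genes=800, cells_per_subject=500,
            marker_frac=0.05, marker_fold=8.0, seed=3,
        )
        adata, truth = synthetic.simulate_sc_reference(cfg)
        qcd, _ = qc_reference(adata)
        sig = select_signature_genes(qcd)
        truth_markers = truth.marker_of[truth.marker_of != ""]
        truth_markers = truth_markers[truth_markers.index.isin(qcd.var_names)]
        recovered = truth_markers.index.isin(sig["gene"])
        assert recovered.mean() > 0.9
        # attribution matches the simulated cell type
        merged = sig.set_index("gene").join(truth_markers.rename("truth"), how="inner")
        correct = (merged["cluster"] == merged["truth"].astype(str)).mean()
        assert correct > 0.95

    def test_no_signal_yields_few_hits(self):
        cfg = synthetic.CellSimConfig(
            n_subjects=4, n_celltypes=3, n_genes=500, cells_per_subject=300,
            marker_fold=1.0, discordant_frac=0.0, seed=5,
        )
        adata, _ = synthetic.simulate_sc_reference(cfg)
        qcd, _ = qc_reference(adata)
        sig = select_signature_genes(qcd)
        assert len(sig) < 0.02 * qcd.n_vars

    def test_tiny_cluster_excluded_with_warning(self):
        X = np.random.default_rng(0).poisson(2.0, size=(62, 400)).astype(np.int32)
        clusters = ["a"] * 30 + ["b"] * 30 + ["rare"] * 2
        ad = _adata(X, ["s1"] * 62, clusters)
        with pytest.warns(UserWarning, match="rare"):
            sig = select_signature_genes(ad)
        assert not (sig["cluster"] == "rare").any()


class TestPseudobulk:
    def test_single_cell_proportional_to_counts(self):
        X = np.array([[4, 0, 6]], dtype=np.int32)
        ad = _adata(X, ["s1"], ["t1"])
        pseudo, profiles = build_pseudobulk(ad)
        np.testing.assert_allclose(pseudo.loc["s1"], [0.4e6, 0.0, 0.6e6])

    def test_hand_summed_three_cell_fixture(self):
        X = np.array([[1, 1], [3, 1], [0, 4]], dtype=np.int32)
        ad = _adata(X, ["s1", "s1", "s1"], ["a", "a", "b"])
        pseudo, profiles = build_pseudobulk(ad)
        np.testing.assert_allclose(pseudo.loc["s1"], [0.4e6, 0.6e6])
        np.testing.assert_allclose(profiles.mean_rel.loc["a"], [4 / 6, 2 / 6])
        np.testing.assert_allclose(profiles.mean_rel.loc["b"], [0.0, 1.0])
        assert profiles.cell_size["a"] == pytest.approx(3.0)

    def test_zero_variance_for_identical_subjects(self):
        X = np.tile(np.array([[2, 3, 5]], dtype=np.int32), (4, 1))
        ad = _adata(X, ["s1", "s1", "s2", "s2"], ["t"] * 4)
        _, profiles = build_pseudobulk(ad)
        np.testing.assert_allclose(profiles.var_rel.to_numpy(), 0.0, atol=1e-15)


class TestConcordanceFilter:
    def test_identical_inputs_hit_degenerate_branch(self):
        bulk = pd.DataFrame({"s1": [10.0, 20.0, 30.0]}, index=["g0", "g1", "g2"])
        pseudo = pd.DataFrame([[10.0, 20.0, 30.0]], index=["p1"],
                              columns=["g0", "g1", "g2"])
        with pytest.warns(UserWarning, match="degenerate"):
            kept, table = concordance_filter(bulk, pseudo)
        assert len(kept) == 3 and table["kept"].all()

    def test_malat1_like_gene_excluded(self):
        # a nuclear-retained transcript: bulk TPM 254 vs pseudo-bulk 391,375
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)] + ["MALAT1"]
        base = rng.uniform(50, 500, 50)
        bulk = pd.DataFrame(
            {"s1": np.r_[base * rng.lognormal(0, 0.05, 50), 254.0]}, index=genes
        )
        pseudo = pd.DataFrame(
            [np.r_[base * rng.lognormal(0, 0.05, 50), 391_375.0]],
            index=["p1"], columns=genes,
        )
        kept, table = concordance_filter(bulk, pseudo)
        assert "MALAT1" not in kept
        assert not table.loc["MALAT1", "kept"]
        assert table.drop("MALAT1")["kept"].mean() > 0.6

    def test_standard_normal_differences_keep_two_thirds(self):
        rng = np.random.default_rng(1)
        n = 5000
        genes = [f"g{i}" for i in range(n)]
        d = rng.normal(size=n)
        bulk = pd.DataFrame({"s1": np.expm1(5 + d)}, index=genes)
        pseudo = pd.DataFrame([np.expm1(np.full(n, 5.0))], index=["p"], columns=genes)
        kept, _ = concordance_filter(bulk, pseudo)
        assert len(kept) / n == pytest.approx(0.683, abs=0.03)


def _toy_profiles(M, sizes=None, var=None):
    K, G = M.shape
    genes = [f"g{j}" for j in range(G)]
    types = [f"t{k}" for k in range(K)]
    M = M / M.sum(axis=1, keepdims=True)
    return ReferenceProfiles(
        mean_rel=pd.DataFrame(M, index=types, columns=genes),
        var_rel=pd.DataFrame(np.zeros_like(M) if var is None else var,
                             index=types, columns=genes),
        cell_size=pd.Series(np.ones(K) if sizes is None else sizes, index=types),
    )


class TestWNNLS:
    def test_pure_type_identified(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(0.1, 1.0, size=(3, 30))
        prof = _toy_profiles(M)
        bulk = pd.Series(prof.mean_rel.loc["t1"].to_numpy(), index=prof.genes)
        res = wnnls_deconvolve(bulk, prof)
        assert res.proportions["t1"] >= 0.99

    def test_scale_invariant_to_library_size(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(0.1, 1.0, size=(4, 40))
        prof = _toy_profiles(M, sizes=np.array([1.0, 2.0, 0.5, 1.5]))
        mix = 0.3 * M[0] / M[0].sum() + 0.7 * M[2] / M[2].sum()
        bulk = pd.Series(mix, index=prof.genes)
        a = wnnls_deconvolve(bulk, prof).proportions
        b = wnnls_deconvolve(bulk * 1e6, prof).proportions
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_cell_size_conversion(self):
        # RNA fractions scale with cell size; count proportions must not
        M = np.tile(np.linspace(1, 2, 20), (2, 1))
        M[1] = M[1][::-1]
        sizes = np.array([4.0, 1.0])
        prof = _toy_profiles(M, sizes=sizes)
        p_true = np.array([0.5, 0.5])
        rna = p_true * sizes
        mix = (rna[:, None] * prof.mean_rel.to_numpy()).sum(axis=0)
        res = wnnls_deconvolve(pd.Series(mix, index=prof.genes), prof)
        np.testing.assert_allclose(res.proportions, p_true, atol=1e-6)

    def test_duplicate_profiles_flagged_not_silently_split(self):
        M = np.vstack([np.linspace(1, 2, 15)] * 2)
        prof = _toy_profiles(M)
        bulk = pd.Series(prof.mean_rel.iloc[0].to_numpy(), index=prof.genes)
        with pytest.warns(UserWarning, match="not identifiable"):
            res = wnnls_deconvolve(bulk, prof)
        assert not res.identifiable

    def test_all_zero_bulk_errors(self):
        prof = _toy_profiles(np.ones((2, 10)))
        with pytest.raises(DeconvolutionError):
            wnnls_deconvolve(pd.Series(np.zeros(10), index=prof.genes), prof)

    def test_nnls_matches_active_set_enumeration(self):
        # brute-force oracle: try every active set, keep feasible best
        rng = np.random.default_rng(4)
        D = rng.uniform(0, 1, size=(10, 3))
        y = rng.uniform(0, 1, size=10)
        from scipy.optimize import nnls

        coef, _ = nnls(D, y)
        best, best_rss = None, np.inf
        for r in range(4):
            for active in itertools.combinations(range(3), r):
                c = np.zeros(3)
                if active:
                    sol, *_ = np.linalg.lstsq(D[:, active], y, rcond=None)
                    if (sol < -1e-12).any():
                        continue
                    c[list(active)] = sol
                rss = np.sum((y - D @ c) ** 2)
                if rss < best_rss - 1e-12:
                    best, best_rss = c, rss
        np.testing.assert_allclose(coef, best, atol=1e-8)


class TestLOO:
    def test_recovery_and_leakage_guard(self, small_reference, small_bulk):
        _, adata, qcd, truth = small_reference
        res = loo_validate(qcd, small_bulk.tpm)
        assert res.overall_rmse < 0.06
        assert res.overall_r > 0.9
        np.testing.assert_allclose(res.estimated.sum(axis=1), 1.0, atol=1e-8)
        # leakage guard: the fold estimate for S1 equals a manual rebuild
        # that never sees S1's nuclei
        ref = qcd[qcd.obs.subject != "S1"].copy()
        sig = select_signature_genes(ref)
        pseudo, prof = build_pseudobulk(ref)
        kept, _ = concordance_filter(small_bulk.tpm, pseudo)
        genes = (
            pd.Index(sig["gene"].unique())
            .intersection(kept)
            .intersection(small_bulk.tpm.index)
        )
        manual = wnnls_deconvolve(small_bulk.tpm["S1_bulk"], prof, genes).proportions
        np.testing.assert_allclose(
            res.estimated.loc["S1"], manual[res.estimated.columns], atol=1e-10
        )

    def test_too_few_subjects(self, small_reference, small_bulk):
        _, _, qcd, _ = small_reference
        sub = qcd[qcd.obs.subject.isin(["S1", "S2"])].copy()
        with pytest.raises(DeconvolutionError):
            loo_validate(sub, small_bulk.tpm)

    def test_everything_filtered_fails_loudly(self, small_reference, small_bulk):
        _, _, qcd, _ = small_reference
        empty_bulk = small_bulk.tpm.iloc[:0]
        with pytest.raises(DeconvolutionError):
            loo_validate(qcd, empty_bulk)


class TestAdjustProportions:
    def test_matches_columnwise_residualize(self):
        rng = np.random.default_rng(6)
        props = pd.DataFrame(rng.dirichlet(np.ones(3), size=50),
                             columns=["a", "b", "c"])
        tech = pd.DataFrame(rng.normal(size=(50, 2)), columns=["t1", "t2"])
        adj = adjust_proportions(props, tech)
        for ct in props.columns:
            expected = residualize(props[ct].to_numpy(), tech) + props[ct].mean()
            np.testing.assert_allclose(adj[ct], expected, atol=1e-12)

    def test_zero_effect_leaves_proportions(self):
        rng = np.random.default_rng(7)
        props = pd.DataFrame(rng.dirichlet(np.ones(2), size=2000), columns=["a", "b"])
        tech = pd.DataFrame(rng.normal(size=(2000, 1)), columns=["t"])
        adj = adjust_proportions(props, tech)
        np.testing.assert_allclose(adj["a"], props["a"], atol=0.05)
        # residuals orthogonal to the factor
        assert abs(np.dot(adj["a"] - adj["a"].mean(), tech["t"])) < 1e-6
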