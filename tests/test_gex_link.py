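import anndata as ad
import numpy as np
import pandas as pd
import pytest

from tcrspec import gex_link as gx
from tcrspec import synthetic_data as sd
from tcrspec import tcr_io


def make_adata(counts, samples=None, barcodes=None, condition=None):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    obs = pd.DataFrame({
        "sample_id": samples or ["S1"] * n,
        "condition": condition or ["WT"] * n,
    }, index=barcodes or [f"B{i}" for i in range(n)])
    var = pd.DataFrame(index=[f"G{j}" for j in range(counts.shape[1])])
    return ad.AnnData(X=counts, obs=obs, var=var)


def clonotype_with_cells(ct_id, cells, cdr3b="CASSAF"):
    ct = tcr_io.Clonotype(ct_id, "CAVAF", cdr3b, "V", "J", "V", "J")
    ct.members = list(cells)
    ct.per_sample_counts = {}
    return ct


class TestAttachClonotypes:
    def test_disjoint_barcodes_zero_matched(self):
        adata = make_adata(np.ones((3, 2)))
        ct = clonotype_with_cells("c1", [("S1", "ZZZ")])
        frac = gx.attach_clonotypes(adata, [ct])
        assert frac["S1"] == 0.0
        assert (adata.obs["clone_size"] == 0).all()

    def test_fixture_matched_fraction(self):
        adata = make_adata(np.ones((10, 2)))
        ct = clonotype_with_cells("c1", [("S1", f"B{i}") for i in range(7)])
        frac = gx.attach_clonotypes(adata, [ct])
        assert frac["S1"] == pytest.approx(0.7)
        assert (adata.obs["clonotype_id"] == "c1").sum() == 7
        assert set(adata.obs["clone_size"]) == {0, 7}

    def test_suffix_normalizer_enables_match(self):
        adata = make_adata(np.ones((1, 2)), barcodes=["AAAC-1"])
        ct = clonotype_with_cells("c1", [("S1", "AAAC")])
        assert gx.attach_clonotypes(adata, [ct], normalize_barcodes=True)["S1"] == 1.0

    def test_duplicate_barcode_fails(self):
        adata = make_adata(np.ones((2, 2)), barcodes=["B0", "B0-x"])
        adata.obs_names = ["B0", "B0"]
        with pytest.raises(ValueError, match="duplicate"):
            gx.attach_clonotypes(adata, [])

    def test_conservation_matched_plus_unmatched(self):
        adata = make_adata(np.ones((10, 2)))
        ct = clonotype_with_cells("c1", [("S1", f"B{i}") for i in range(4)])
        gx.attach_clonotypes(adata, [ct])
        matched = (adata.obs["clone_size"] > 0).sum()
        assert matched + (adata.obs["clone_size"] == 0).sum() == adata.n_obs


class TestCloneSizeCorrelation:
    def _adata_with_sizes(self, x, sizes):
        adata = make_adata(x)
        adata.obs["clone_size"] = sizes
        adata.obs["clonotype_id"] = [f"c{s}" for s in sizes]
        return adata

    def test_monotone_identity_rho_one(self):
        sizes = np.arange(1, 21)
        x = np.tile(sizes[:, None], (1, 3)).astype(float)
        adata = self._adata_with_sizes(x, sizes)
        adata.layers["lognorm"] = x  # bypass normalization for the identity
        corr = gx.clone_size_correlation(adata)
        assert np.allclose(corr["rho"], 1.0)

    def test_constant_gene_flagged_zero(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, size=(30, 2)).astype(float)
        x[:, 1] = 5.0
        adata = self._adata_with_sizes(x, rng.integers(1, 10, 30))
        adata.layers["lognorm"] = x
        corr = gx.clone_size_correlation(adata).set_index("gene")
        assert corr.loc["G1", "rho"] == 0.0
        assert bool(corr.loc["G1", "degenerate"])

    def test_small_stratum_skipped(self):
        x = np.ones((5, 2))
        adata = self._adata_with_sizes(x, np.arange(1, 6))
        corr = gx.clone_size_correlation(adata, min_cells=10)
        assert len(corr) == 0

    def test_rho_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, size=(50, 4))
        sizes = rng.integers(1, 30, 50)
        a1 = self._adata_with_sizes(x.copy(), sizes)
        a1.layers["lognorm"] = x
        a2 = self._adata_with_sizes(x.copy(), sizes)
        a2.layers["lognorm"] = np.exp(x / 3)  # strictly monotone transform
        c1 = gx.clone_size_correlation(a1).set_index("gene")["rho"]
        c2 = gx.clone_size_correlation(a2).set_index("gene")["rho"]
        assert np.allclose(c1, c2, atol=1e-12)


class TestDifferentialExpression:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(3.0, size=(40, 20)).astype(float)
        adata = make_adata(np.vstack([x, x]))
        mask_a = np.arange(80) < 40
        de = gx.differential_expression(adata, mask_a, ~mask_a)
        assert (de["p_adjusted"] == 1.0).all()
        passing = (de["p_adjusted"] < 0.01) & (de["log2fc"].abs() > 0.2)
        assert passing.sum() == 0

    def test_shifted_gene_detected(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(2.0, size=(200, 10)).astype(float)
        x[100:, 0] = rng.poisson(8.0, size=100)
        adata = make_adata(x)
        mask_a = np.arange(200) < 100
        de = gx.differential_expression(adata, mask_a, ~mask_a).set_index("gene")
        assert de.loc["G0", "p_adjusted"] < 0.01
        assert de.loc["G0", "log2fc"] > 0.2

    def test_small_group_guard(self):
        adata = make_adata(np.ones((10, 3)))
        mask_a = np.arange(10) < 2
        with pytest.raises(ValueError, match="min_cells"):
            gx.differential_expression(adata, mask_a, ~mask_a)

    def test_permuted_labels_calibrated(self):
        rng = np.random.default_rng(3)
        x = rng.negative_binomial(2, 0.3, size=(400, 200)).astype(float)
        adata = make_adata(x)
        perm = rng.permutation(400) < 200
        de = gx.differential_expression(adata, perm, ~perm)
        from scipy.stats import kstest
        assert kstest(de["p"], "uniform").pvalue > 0.01


class TestAverageExpression:
    def test_single_cell_entity_identity(self):
        x = np.array([[1.0, 4.0, 2.0]])
        adata = make_adata(x)
        adata.obs["clonotype_id"] = ["c1"]
        avg = gx.average_expression_by(adata)
        assert avg.loc["c1"].drop("n_cells").tolist() == [1.0, 4.0, 2.0]

    def test_mean_of_two_cells(self):
        adata = make_adata(np.array([[2.0], [4.0]]))
        adata.obs["clonotype_id"] = ["c1", "c1"]
        avg = gx.average_expression_by(adata)
        assert avg.loc["c1", "G0"] == 3.0
        assert avg.loc["c1", "n_cells"] == 2

    def test_unmatched_cells_excluded(self):
        adata = make_adata(np.ones((5, 2)))
        adata.obs["clonotype_id"] = ["c1", "c1", "c2", "", ""]
        avg = gx.average_expression_by(adata)
        assert len(avg) == 2


class TestModuleScore:
    def _synthetic_adata(self, seed=0, effect=1.0):
        cfg = sd.SynthConfig(n_samples_per_condition=3, clones_per_sample=80,
                             n_genes=120, n_size_correlated_genes=0,
                             n_condition_shifted_genes=6, effect_size=effect,
                             seed=seed)
        _, gt = sd.generate_repertoire(cfg)
        counts, obs, genes = sd.generate_expression(gt.cells, cfg)
        adata = ad.AnnData(X=counts.astype(float),
                           obs=obs.set_index("barcode"),
                           var=pd.DataFrame(index=genes))
        return adata, gt

    def test_whole_transcriptome_scores_near_zero(self):
        adata, _ = self._synthetic_adata()
        scores = gx.module_score(adata, list(adata.var_names), seed=0)
        assert np.abs(scores).max() < 0.05

    def test_condition_shifted_gene_set_recovered(self):
        hits = 0
        for seed in range(10):
            adata, gt = self._synthetic_adata(seed=seed)
            scores = gx.module_score(adata, list(gt.condition_shifted_genes), seed=1)
            is_auto = (adata.obs["condition"] == "AUTO").to_numpy()
            if scores[is_auto].mean() > scores[~is_auto].mean():
                hits += 1
        assert hits >= 9

    def test_deterministic_under_seed(self):
        adata, gt = self._synthetic_adata()
        s1 = gx.module_score(adata, list(gt.condition_shifted_genes), seed=3)
        s2 = gx.module_score(adata, list(gt.condition_shifted_genes), seed=3)
        assert np.array_equal(s1, s2)

    def test_empty_overlap_fails(self):
        adata, _ = self._synthetic_adata()
        with pytest.raises(ValueError):
            gx.module_score(adata, ["NOSUCHGENE"])


def test_mtx_round_trip(tmp_path):
    cfg = sd.SynthConfig(n_samples_per_condition=2, clones_per_sample=30,
                         n_genes=40, seed=5)
    _, gt = sd.generate_repertoire(cfg)
    counts, obs, genes = sd.generate_expression(gt.cells, cfg)
    sd.write_expression_mtx(counts, obs, genes, tmp_path)
    adata = gx.load_expression_mtx(tmp_path)
    assert adata.shape == (len(obs), len(genes))
    x = adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X
    assert np.array_equal(x, counts)
    assert "condition" in adata.obs.columns
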