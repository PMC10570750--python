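"""Single-cell QC, marker-threshold merging, proportion tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from isletomics.scmarkers import (
    CellDataset,
    cluster_condition_proportions,
    marker_summary,
    merge_clusters_by_marker,
    qc_filter,
)
from isletomics.synthdata import TruthConfig, generate_annotation, generate_cells


def dataset(counts, genes, clusters=None, samples=None, conditions=None):
    n = counts.shape[0]
    obs = pd.DataFrame(
        {
            "sample": samples or ["s1"] * n,
            "condition": conditions or ["vehicle"] * n,
            "cluster": clusters or ["c0"] * n,
        },
        index=[f"cell{i}" for i in range(n)],
    )
    return CellDataset(ad.AnnData(
        X=sparse.csr_matrix(np.asarray(counts)),
        obs=obs, var=pd.DataFrame(index=pd.Index(genes)),
    ))


@pytest.fixture(scope="module")
def planted_cells():
    cfg = TruthConfig(seed=9, n_known_genes=6, chrom_length=400_000,
                      n_novel_per_category={}, enhancer_state_counts={},
                      n_cells=2400)
    _, _, _, truth = generate_annotation(cfg)
    return cfg, truth, generate_cells(truth, cfg)


class TestQcFilter:
    def test_boundaries(self):
        # gene counts chosen so (features, counts, mito) hit the documented edges
        counts = np.zeros((3, 6))
        counts[0, :3] = [10, 10, 10]           # too few features/counts
        counts[1, :] = [2000, 2000, 2000, 2000, 1000, 1000]  # mito exactly 10%
        counts[2, :] = [3000, 3000, 3000, 3000, 500, 400]    # ok
        ds = dataset(counts, ["g1", "g2", "g3", "g4", "mt-a", "mt-b"])
        kept = qc_filter(ds, f_min=2, f_max=10, c_min=5000, c_max=50000,
                         mito_max=0.10)
        assert list(kept.adata.obs_names) == ["cell2"]

    def test_planted_failures_filtered_exactly(self, planted_cells):
        cfg = TruthConfig(seed=9, n_known_genes=6, chrom_length=400_000,
                          n_novel_per_category={}, enhancer_state_counts={},
                          n_cells=100, n_qc_fail_cells=40)
        _, _, _, truth = generate_annotation(cfg)
        ds = generate_cells(truth, cfg)
        kept = qc_filter(ds)
        assert kept.n_cells == 100
        assert set(kept.adata.obs_names) == set(
            truth.cells.index[truth.cells.qc_ok]
        )

    def test_idempotent(self, planted_cells):
        _, _, ds = planted_cells
        once = qc_filter(ds)
        twice = qc_filter(once)
        assert list(once.adata.obs_names) == list(twice.adata.obs_names)


class TestMerge:
    def test_threshold_application_and_boundary(self):
        # three clusters with normalized means 0.35 / 0.25 / 0.10
        counts = np.zeros((3, 2))
        ds = dataset(counts, ["m", "g"], clusters=["a", "b", "c"])
        # bypass count-derived means by planting counts giving those means
        # ln(1+1e4*c/total): choose totals 1e4 so mean = ln(1+c)
        vals = [np.expm1(0.35), np.expm1(0.25), np.expm1(0.10)]
        x = np.zeros((3, 2))
        for i, v in enumerate(vals):
            x[i] = [v, 1e4 - v]
        ds = dataset(x, ["m", "g"], clusters=["a", "b", "c"])
        res = merge_clusters_by_marker(ds, "m")
        assert res.cluster_labels == {"a": "High", "b": "Mid", "c": "Low"}

    def test_mean_exactly_at_hi_is_mid(self):
        v = np.expm1(0.3)
        ds = dataset(np.array([[v, 1e4 - v]]), ["m", "g"], clusters=["a"])
        res = merge_clusters_by_marker(ds, "m")
        assert res.cluster_labels["a"] == "Mid"

    def test_absent_marker_is_an_error(self):
        ds = dataset(np.ones((2, 2)), ["g1", "g2"])
        with pytest.raises(KeyError, match="absent"):
            merge_clusters_by_marker(ds, "nope")

    def test_planted_three_level_gradient_recovered(self, planted_cells):
        cfg, truth, ds = planted_cells
        res = merge_clusters_by_marker(ds, cfg.marker_name)
        acc = (res.cell_labels.values ==
               truth.cells["level"].values).mean()
        assert acc >= 0.99

    def test_raising_hi_never_increases_high_cells(self, planted_cells):
        cfg, _, ds = planted_cells
        counts = []
        for hi in (0.25, 0.3, 0.35, 0.45, 0.6):
            res = merge_clusters_by_marker(ds, cfg.marker_name, hi=hi, lo=0.18)
            counts.append((res.cell_labels == "High").sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestProportions:
    def test_fractions_sum_to_one_and_null_t(self):
        rng = np.random.default_rng(1)
        n = 400
        counts = rng.poisson(5, size=(n, 3))
        samples = [f"s{i % 4}" for i in range(n)]
        conditions = ["vehicle" if i % 4 < 2 else "treated" for i in range(n)]
        clusters = [["a", "b"][i % 2] for i in range(n)]
        ds = dataset(counts, ["m", "g1", "g2"], clusters=clusters,
                     samples=samples, conditions=conditions)
        res = merge_clusters_by_marker(ds, "m", hi=10.0, lo=0.001)
        props, tests = cluster_condition_proportions(res, ds)
        assert np.allclose(props[["High", "Mid", "Low"]].sum(axis=1), 1.0,
                           atol=1e-12)
        # identical per-sample fractions by construction -> t == 0
        mid = tests[tests.merged == "Mid"].iloc[0]
        assert mid.t == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_condition_skips_test(self):
        ds = dataset(np.ones((4, 2)), ["m", "g"],
                     samples=["s1", "s1", "s2", "s3"],
                     conditions=["vehicle", "vehicle", "treated", "treated"])
        res = merge_clusters_by_marker(ds, "m", hi=10.0, lo=0.001)
        _, tests = cluster_condition_proportions(res, ds)
        assert tests["skipped"].all()

    def test_planted_high_fraction_shift_detected(self):
        cfg = TruthConfig(seed=9, n_known_genes=6, chrom_length=400_000,
                          n_novel_per_category={}, enhancer_state_counts={},
                          n_cells=4800,
                          sc_conditions={"vehicle": 3, "palmitate": 3},
                          maturity_props={"vehicle": (0.4, 0.35, 0.25),
                                          "palmitate": (0.2, 0.45, 0.35)},
                          prop_sd=0.02)
        _, _, _, truth = generate_annotation(cfg)
        ds = generate_cells(truth, cfg)
        res = merge_clusters_by_marker(ds, cfg.marker_name)
        _, tests = cluster_condition_proportions(res, ds)
        high = tests[(tests.merged == "High") & (tests.condition == "palmitate")]
        assert float(high["p"].iloc[0]) < 0.05
        assert float(high["t"].iloc[0]) < 0


class TestMarkerSummary:
    def test_absent_gene_yields_na_row(self):
        ds = dataset(np.ones((2, 2)), ["g1", "g2"])
        out = marker_summary(ds, ["g1", "nope"])
        assert out[out.gene == "nope"]["mean_norm"].isna().all()

    def test_single_cell_closed_form(self):
        x = np.zeros((1, 2))
        x[0] = [1, 9999]
        ds = dataset(x, ["g1", "g2"])
        out = marker_summary(ds, ["g1"])
        assert out.iloc[0].mean_norm == pytest.approx(np.log(2.0))
        assert out.iloc[0].frac_expressing == 1.0

    def test_matches_dense_recomputation(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(1.0, size=(30, 5))
        clusters = [f"c{i % 3}" for i in range(30)]
        ds = dataset(x, [f"g{j}" for j in range(5)], clusters=clusters)
        out = marker_summary(ds, [f"g{j}" for j in range(5)])
        totals = x.sum(axis=1)
        for _, row in out.iterrows():
            j = int(row.gene[1:])
            mask = np.array([c == row.cluster for c in clusters])
            norm = np.log1p(1e4 * x[mask, j] / np.maximum(totals[mask], 1))
            assert row.mean_norm == pytest.approx(norm.mean())
            assert row.frac_expressing == pytest.approx((x[mask, j] > 0).mean())
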