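import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methdiffscan as mds


def overlaps(a, b):
    return a[0] <= b[1] and b[0] <= a[1]


class TestAnnotationSim:
    def test_zero_transcripts_empty(self):
        cfg = mds.SimConfig(seed=1, n_transcripts=0)
        assert len(mds.simulate_annotation(cfg)) == 0

    def test_same_seed_identical(self):
        cfg = mds.SimConfig(seed=5, n_transcripts=30)
        a = mds.simulate_annotation(cfg)
        b = mds.simulate_annotation(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_dense_packing_non_overlapping(self):
        """200 bodies on 2 Mb, verified by pairwise interval scan."""
        cfg = mds.SimConfig(seed=3, n_chroms=1, chrom_length_bp=2_000_000,
                            n_transcripts=200)
        ann = mds.simulate_annotation(cfg)
        assert len(ann) == 200
        ivals = list(zip(ann["tx_start"], ann["tx_end"]))
        for i in range(len(ivals)):
            for j in range(i + 1, len(ivals)):
                assert not overlaps(ivals[i], ivals[j])
        assert ann["transcript_id"].is_unique
        assert set(ann["strand"]) == {"+", "-"}
        assert all(len(e) >= 1 for e in ann["exons"])

    def test_infeasible_packing_raises(self):
        cfg = mds.SimConfig(seed=1, n_chroms=1, chrom_length_bp=50_000,
                            n_transcripts=50)
        with pytest.raises(ValueError, match="pack"):
            mds.simulate_annotation(cfg)

    def test_strand_rule_for_tss(self):
        cfg = mds.SimConfig(seed=9, n_transcripts=60)
        ann = mds.simulate_annotation(cfg)
        plus = ann[ann["strand"] == "+"]
        minus = ann[ann["strand"] == "-"]
        assert (plus["tss"] == plus["tx_start"]).all()
        assert (minus["tss"] == minus["tx_end"]).all()


class TestCountSim:
    def test_no_planting_empty_truth(self):
        cfg = mds.SimConfig(seed=2, n_chroms=1, chrom_length_bp=50_000,
                            n_transcripts=0)
        samples, truth = mds.simulate_counts(cfg, mds.simulate_annotation(cfg))
        assert len(truth) == 0
        assert len(samples) == 6

    def test_determinism(self):
        cfg = mds.SimConfig(seed=4, n_chroms=1, chrom_length_bp=100_000,
                            n_transcripts=10,
                            planted_dmc=[mds.PlantedSite(40.0)])
        ann = mds.simulate_annotation(cfg)
        s1, t1 = mds.simulate_counts(cfg, ann)
        s2, t2 = mds.simulate_counts(cfg, ann)
        pd.testing.assert_frame_equal(t1, t2)
        for name in s1:
            pd.testing.assert_frame_equal(s1[name], s2[name])

    def test_counts_conserve_coverage(self, sim_dataset):
        _cfg, _ann, samples, _truth = sim_dataset
        for df in samples.values():
            assert (df["n_meth"] >= 0).all()
            assert (df["n_unmeth"] >= 0).all()
            assert ((df["n_meth"] + df["n_unmeth"]) >= 1).all()

    def test_modal_coverage_near_configured_mean(self):
        cfg = mds.SimConfig(seed=7, n_chroms=1, chrom_length_bp=1_200_000,
                            n_transcripts=0, mean_coverage=10)
        samples, _ = mds.simulate_counts(cfg, mds.simulate_annotation(cfg))
        cov = np.concatenate([
            (df["n_meth"] + df["n_unmeth"]).to_numpy() for df in samples.values()
        ])
        assert len(cov) >= 10_000
        mode = np.bincount(cov).argmax()
        assert abs(mode - 10) <= 1

    def test_bimodal_methylation_profile(self):
        """Global histogram peak at 95-100%, secondary local peak at 0-5%."""
        cfg = mds.SimConfig(seed=8, n_chroms=1, chrom_length_bp=1_200_000,
                            n_transcripts=0, mean_coverage=30)
        samples, _ = mds.simulate_counts(cfg, mds.simulate_annotation(cfg))
        pct = np.concatenate([
            100.0 * df["n_meth"] / (df["n_meth"] + df["n_unmeth"])
            for df in samples.values()
        ])
        hist, _edges = np.histogram(pct, bins=np.arange(0, 102, 2))
        assert hist.argmax() * 2 >= 94  # global maximum in the top bins
        low = hist[:3].max()            # bins covering [0, 6)
        mid = hist[5:45].max()          # bins covering [10, 90)
        assert low > mid                # a secondary local mode near zero

    def test_hifreq_clusters_land_within_tss_window(self):
        cfg = mds.SimConfig(
            seed=12, n_chroms=1, chrom_length_bp=500_000, n_transcripts=12,
            mean_coverage=30,
            planted_hifreq=[mds.PlantedCluster(6, 50.0, "hyper")
                            for _ in range(4)],
        )
        ann = mds.simulate_annotation(cfg)
        samples, truth = mds.simulate_counts(cfg, ann)
        clusters = truth[truth["category"] == "HIFREQ"]
        assert len(clusters) == 4
        any_sample = next(iter(samples.values()))
        tss = ann.set_index("transcript_id")["tss"]
        for rec in clusters.itertuples():
            t = tss[rec.transcript_id]
            # brute-force: enough CpG sites exist inside TSS +/- 10 kb
            n_in = ((any_sample["chrom"] == rec.chrom)
                    & (any_sample["pos"] >= t - 10_000)
                    & (any_sample["pos"] <= t + 10_000)).sum()
            assert n_in >= rec.n_sites

    def test_planted_loci_disjoint_across_categories(self):
        cfg = mds.SimConfig(
            seed=13, n_chroms=2, chrom_length_bp=400_000, n_transcripts=30,
            planted_dmc=[mds.PlantedSite(40.0) for _ in range(10)],
            planted_dmr_tiles=[mds.PlantedTile(40.0) for _ in range(3)],
            planted_dmp_promoters=[mds.PlantedPromoter(40.0) for _ in range(3)],
            planted_hifreq=[mds.PlantedCluster(5, 50.0) for _ in range(3)],
        )
        ann = mds.simulate_annotation(cfg)
        _samples, truth = mds.simulate_counts(cfg, ann)
        assert len(truth) == 19
        dmc_rows = truth[truth["category"] == "DMC"]
        regions = truth[truth["category"] != "DMC"]
        for site in dmc_rows.itertuples():
            inside = ((regions["chrom"] == site.chrom)
                      & (regions["start"] <= site.start)
                      & (regions["end"] >= site.end))
            assert not inside.any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="delta_percent"):
            mds.SimConfig(seed=1, planted_dmc=[mds.PlantedSite(0.0)])
        with pytest.raises(ValueError, match="n_clustered"):
            mds.SimConfig(seed=1, planted_hifreq=[mds.PlantedCluster(0, 40.0)])
        with pytest.raises(ValueError, match="weights"):
            mds.SimConfig(seed=1, baseline_mixture=((0.5, 1, 1), (0.2, 1, 1)))


class TestExpressionSim:
    def _truth(self, deltas, directions):
        return pd.DataFrame({
            "category": "DMP", "chrom": "chr1",
            "start": 1, "end": 2,
            "transcript_id": [f"tx{i}" for i in range(len(deltas))],
            "gene_id": [f"g{i}" for i in range(len(deltas))],
            "delta_percent": deltas, "direction": directions, "n_sites": 1,
        })

    def test_null_coupling_uncorrelated(self):
        rng = np.random.default_rng(0)
        deltas = rng.uniform(20, 90, 100)
        directions = rng.choice(["hyper", "hypo"], 100)
        truth = self._truth(deltas, directions)
        ann = pd.DataFrame(columns=["gene_id"])
        expr = mds.simulate_expression(truth, ann, rho=0.0, seed=3)
        signed = np.where(truth["direction"] == "hyper", 1, -1) * truth["delta_percent"]
        rho, _ = stats.spearmanr(signed, expr.set_index("gene_id").loc[
            truth["gene_id"], "log2_fold_change"])
        assert abs(rho) < 0.3

    def test_perfect_anticoupling_anti_monotone(self):
        deltas = np.arange(10, 90, 10).astype(float)
        truth = self._truth(deltas, ["hyper"] * len(deltas))
        ann = pd.DataFrame(columns=["gene_id"])
        expr = mds.simulate_expression(truth, ann, rho=-1.0, seed=5)
        lfc = expr.set_index("gene_id").loc[truth["gene_id"], "log2_fold_change"]
        rho, _ = stats.spearmanr(deltas, lfc)
        assert rho == pytest.approx(-1.0)

    def test_strong_anticoupling_monte_carlo(self):
        """Sample Spearman near the -0.8 target at n=200 genes."""
        rng = np.random.default_rng(42)
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            deltas = rng.uniform(20, 90, 200)
            directions = rng.choice(["hyper", "hypo"], 200)
            truth = self._truth(deltas, directions)
            expr = mds.simulate_expression(truth, pd.DataFrame(columns=["gene_id"]),
                                           rho=-0.8, seed=seed)
            signed = np.where(truth["direction"] == "hyper", 1, -1) * truth["delta_percent"]
            rho, _ = stats.spearmanr(
                signed, expr.set_index("gene_id").loc[truth["gene_id"],
                                                      "log2_fold_change"])
            hits += -0.9 <= rho <= -0.7
        assert hits >= 0.85 * n_seeds

    def test_unplanted_genes_get_null_noise(self):
        truth = self._truth([50.0], ["hyper"])
        ann = pd.DataFrame({"gene_id": [f"n{i}" for i in range(50)]})
        expr = mds.simulate_expression(truth, ann, rho=-0.8, seed=1)
        nulls = expr[expr["gene_id"].str.startswith("n")]
        assert len(nulls) == 50
        assert not nulls["de_flag"].any()
        assert abs(nulls["log2_fold_change"].mean()) < 0.3

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mds.simulate_expression(pd.DataFrame(columns=["transcript_id"]),
                                    pd.DataFrame(columns=["gene_id"]),
                                    rho=1.5, seed=1)


def test_write_dataset_roundtrip(tmp_path):
    cfg = mds.SimConfig(seed=21, n_chroms=1, chrom_length_bp=100_000,
                        n_transcripts=8,
                        planted_dmc=[mds.PlantedSite(40.0)])
    paths = mds.write_dataset(cfg, tmp_path)
    assert paths["annotation"].exists()
    design = mds.read_design(paths["design"])
    assert design.reference == "control"
    calls = mds.read_bismark_cov(paths["control_1"])
    assert len(calls) > 100
    ann = mds.read_annotation(paths["annotation"], "bed12")
    assert len(ann) == 8


def test_null_p_values_approximately_uniform():
    """With dispersion 0, no planted effects and mid-range baselines, the
    downstream per-site p-values are near Uniform(0,1)."""
    from scipy import stats
    cfg = mds.SimConfig(seed=61, n_chroms=3, chrom_length_bp=700_000,
                        n_transcripts=0, mean_coverage=30, dispersion=0.0,
                        baseline_mixture=((1.0, 5.0, 5.0),))
    ann = mds.simulate_annotation(cfg)
    samples, _ = mds.simulate_counts(cfg, ann)
    design = mds.GroupDesign(
        {n: ("control" if n.startswith("control") else "case")
         for n in samples}, reference="control")
    mat = mds.unite(samples, design, min_coverage=10)
    res = mds.diff_test(mat)
    assert len(res) >= 20_000
    ks = stats.kstest(res["p_value"].iloc[:20_000], "uniform").statistic
    assert ks < 0.03
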