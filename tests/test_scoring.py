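import numpy as np
import pandas as pd
import pytest

import methdiffscan as mds


def dmc_frame(rows):
    """rows: (chrom, pos, meth_diff, transcript_id, gene_id, distance)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "meth_diff",
                                     "transcript_id", "gene_id",
                                     "distance_to_tss"])
    df["end"] = df["start"]
    df["direction"] = np.where(df["meth_diff"] > 0, "hyper", "hypo")
    return df


def one_tx_annotation(tss=50_000, chrom="chr1", tx_id="tx1", gene="g1"):
    return pd.DataFrame([{
        "transcript_id": tx_id, "gene_id": gene, "chrom": chrom,
        "strand": "+", "tx_start": tss, "tx_end": tss + 2000,
        "exons": ((tss, tss + 2000),), "tss": tss,
    }])


class TestTopDmcGenes:
    def test_included_inside_both_strict_thresholds(self):
        dmcs = dmc_frame([("chr1", 1, 35.0, "t1", "g1", 9_999)])
        assert mds.top_dmc_genes(dmcs) == {"g1"}

    def test_exact_diff_boundary_excluded(self):
        dmcs = dmc_frame([("chr1", 1, 30.0, "t1", "g1", 500)])
        assert mds.top_dmc_genes(dmcs) == set()

    def test_exact_distance_boundary_excluded(self):
        dmcs = dmc_frame([("chr1", 1, 80.0, "t1", "g1", 10_000)])
        assert mds.top_dmc_genes(dmcs) == set()

    def test_negative_diff_and_distance_use_magnitudes(self):
        dmcs = dmc_frame([("chr1", 1, -45.0, "t1", "g1", -2_000)])
        assert mds.top_dmc_genes(dmcs) == {"g1"}


class TestHighFrequencyGenes:
    def _cluster(self, n, tss=50_000, spacing=500):
        rows = [("chr1", tss + i * spacing, 50.0, "tx1", "g1", i * spacing)
                for i in range(n)]
        return dmc_frame(rows)

    def test_five_members_reported(self):
        res = mds.high_frequency_genes(self._cluster(5), one_tx_annotation())
        assert len(res) == 1
        assert res.iloc[0]["dmc_count"] == 5
        assert res.iloc[0]["dominant_direction"] == "hyper"

    def test_four_members_not_reported(self):
        res = mds.high_frequency_genes(self._cluster(4), one_tx_annotation())
        assert len(res) == 0

    def test_planted_26_member_cluster_counted_exactly(self):
        res = mds.high_frequency_genes(self._cluster(26, spacing=380),
                                       one_tx_annotation())
        assert res.iloc[0]["dmc_count"] == 26

    def test_members_restricted_to_window(self):
        dmcs = self._cluster(6, spacing=3000)  # positions up to TSS+15000
        res = mds.high_frequency_genes(dmcs, one_tx_annotation(), window=10000,
                                       min_count=1)
        assert res.iloc[0]["dmc_count"] == 4  # offsets 0,3000,6000,9000
        assert len(res.iloc[0]["members"]) == 4

    def test_monotone_in_min_count_and_window(self):
        dmcs = self._cluster(8, spacing=2000)
        ann = one_tx_annotation()
        n_by_count = [len(mds.high_frequency_genes(dmcs, ann, min_count=k))
                      for k in (1, 5, 9)]
        assert n_by_count == sorted(n_by_count, reverse=True)
        small = mds.high_frequency_genes(dmcs, ann, window=4000, min_count=1)
        large = mds.high_frequency_genes(dmcs, ann, window=14000, min_count=1)
        assert small.iloc[0]["dmc_count"] <= large.iloc[0]["dmc_count"]

    def test_tied_directions_labelled_mixed(self):
        rows = [("chr1", 50_000 + i * 100, d, "tx1", "g1", i * 100)
                for i, d in enumerate([50, 50, 50, -50, -50, -50])]
        res = mds.high_frequency_genes(dmc_frame(rows), one_tx_annotation())
        assert res.iloc[0]["dominant_direction"] == "mixed"

    def test_multi_assignment_counts_for_overlapping_windows(self):
        ann = pd.concat([one_tx_annotation(tss=50_000),
                         one_tx_annotation(tss=55_000, tx_id="tx2", gene="g2")],
                        ignore_index=True)
        dmcs = self._cluster(5, tss=50_000, spacing=1000)  # 50k..54k
        both = mds.high_frequency_genes(dmcs, ann, min_count=5)
        assert set(both["transcript_id"]) == {"tx1", "tx2"}
        nearest_only = mds.high_frequency_genes(dmcs, ann, min_count=5,
                                                multi_assign=False)
        assert set(nearest_only["transcript_id"]) == {"tx1"}


class TestDistributions:
    def test_isolated_dmcs_all_counts_one(self):
        ann = pd.concat([one_tx_annotation(tss=t, tx_id=f"tx{t}", gene=f"g{t}")
                         for t in (50_000, 200_000, 400_000)],
                        ignore_index=True)
        dmcs = dmc_frame([("chr1", t + 10, 40.0, f"tx{t}", f"g{t}", 10)
                          for t in (50_000, 200_000, 400_000)])
        vec, summary = mds.dmc_frequency_distribution(dmcs, ann)
        assert (vec == 1).all()
        assert summary["median"] == 1.0

    def test_hand_computed_median(self):
        # per-transcript counts {1, 1, 2, 5} -> median 1.5
        tsss = [100_000, 200_000, 300_000, 400_000]
        counts = [1, 1, 2, 5]
        ann = pd.concat([one_tx_annotation(tss=t, tx_id=f"tx{t}", gene=f"g{t}")
                         for t in tsss], ignore_index=True)
        rows = []
        for t, k in zip(tsss, counts):
            rows += [("chr1", t + 100 * i, 40.0, f"tx{t}", f"g{t}", 100 * i)
                     for i in range(k)]
        vec, summary = mds.dmc_frequency_distribution(dmc_frame(rows), ann)
        assert sorted(vec) == counts
        assert summary["median"] == 1.5

    def test_tss_distance_median_zero_when_all_at_tss(self):
        dmcs = dmc_frame([("chr1", 1, 40.0, "t1", "g1", 0)] * 3)
        _d, summary = mds.tss_distance_distribution(dmcs)
        assert summary["median"] == 0.0

    def test_tss_distance_hand_median(self):
        dmcs = dmc_frame([
            ("chr1", 1, 40.0, "t1", "g1", 0),
            ("chr1", 2, 40.0, "t1", "g1", -5_000),
            ("chr1", 3, 40.0, "t1", "g1", 20_000),
        ])
        _d, summary = mds.tss_distance_distribution(dmcs)
        assert summary["median"] == 5_000.0

    def test_planted_proximal_fraction_recovered(self):
        """Cluster-planted DMCs called by the pipeline stay TSS-proximal."""
        cfg = mds.SimConfig(
            seed=17, n_chroms=1, chrom_length_bp=600_000, n_transcripts=15,
            mean_coverage=30,
            planted_hifreq=[mds.PlantedCluster(8, 50.0, "hyper")
                            for _ in range(5)],
        )
        ann = mds.simulate_annotation(cfg)
        samples, _truth = mds.simulate_counts(cfg, ann)
        design = mds.GroupDesign(
            {n: ("control" if n.startswith("control") else "case")
             for n in samples}, reference="control")
        mat = mds.unite(samples, design, min_coverage=10)
        res = mds.diff_test(mat)
        res["q_value"] = mds.adjust_fdr(res["p_value"].to_numpy())
        res = mds.call_differential(res)
        assoc = mds.nearest_tss(mds.called(res), ann)
        dist, _summary = mds.tss_distance_distribution(assoc)
        assert len(dist) >= 20
        assert (dist <= 10_000).mean() >= 0.75


class TestChromosomeCounts:
    def test_single_chromosome_all_hyper(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 4, "direction": ["hyper"] * 4})
        table = mds.chromosome_direction_counts(df)
        assert table.loc["chr1", "hyper"] == 4
        assert table.loc["chr1", "hypo"] == 0

    def test_totals_conserved(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2", "chr3"], 100),
            "direction": rng.choice(["hyper", "hypo", "ns"], 100),
        })
        table = mds.chromosome_direction_counts(df)
        assert table.to_numpy().sum() == (df["direction"] != "ns").sum()


class TestOverlapSets:
    def test_disjoint_sets_empty_center(self):
        rep = mds.overlap_sets({"A": {1, 2}, "B": {3, 4}, "C": {5}})
        assert rep.center == set()

    def test_identical_sets_all_central(self):
        rep = mds.overlap_sets({"A": {1, 2}, "B": {1, 2}})
        assert rep.center == {1, 2}
        assert rep.partitions["A"] == set()

    def test_hand_enumerated_partition(self):
        rep = mds.overlap_sets({"A": {"x", "y"}, "B": {"y", "z"}, "C": {"y"}})
        assert rep.center == {"y"}
        assert rep.partitions["A"] == {"x"}
        assert rep.partitions["B"] == {"z"}
        assert rep.partitions["A&B"] == set()

    def test_partitions_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(4)
        sets = {k: set(rng.integers(0, 50, 20).tolist()) for k in "ABC"}
        rep = mds.overlap_sets(sets)
        union = set().union(*sets.values())
        seen = []
        for members in rep.partitions.values():
            seen += list(members)
        assert sorted(seen) == sorted(union)  # each member exactly once

    def test_jaccard_indices(self):
        rep = mds.overlap_sets({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert rep.jaccard[("A", "B")] == pytest.approx(0.5)

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            mds.overlap_sets({"A": {1}})


class TestCrossCategory:
    def test_same_direction_shared(self):
        out = mds.cross_category_overlap({"g1": "hyper"}, {"g1": "hyper"}, {},
                                         direction_aware=True)
        assert out["DMC&DMR"] == {"g1"}

    def test_conflicting_direction_excluded(self):
        out = mds.cross_category_overlap({"g1": "hyper"}, {"g1": "hypo"}, {},
                                         direction_aware=True)
        assert out["DMC&DMR"] == set()

    def test_direction_aware_subset_of_agnostic(self):
        rng = np.random.default_rng(6)
        def cat():
            return {f"g{i}": rng.choice(["hyper", "hypo"])
                    for i in rng.integers(0, 30, 15)}
        a, b, c = cat(), cat(), cat()
        aware = mds.cross_category_overlap(a, b, c, direction_aware=True)
        agnostic = mds.cross_category_overlap(a, b, c, direction_aware=False)
        for key in aware:
            assert aware[key] <= agnostic[key]


def test_uniform_planting_gives_uniform_chromosome_counts():
    """DMCs planted uniformly over equal-length chromosomes produce
    per-chromosome call counts consistent with uniformity (chi-square)."""
    from scipy import stats as sps
    rejections = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = mds.SimConfig(
            seed=100 + seed, n_chroms=3, chrom_length_bp=400_000,
            n_transcripts=0, mean_coverage=30,
            planted_dmc=[mds.PlantedSite(50.0, "hyper") for _ in range(45)]
            + [mds.PlantedSite(50.0, "hypo") for _ in range(45)],
        )
        ann = mds.simulate_annotation(cfg)
        samples, _truth = mds.simulate_counts(cfg, ann)
        design = mds.GroupDesign(
            {n: ("control" if n.startswith("control") else "case")
             for n in samples}, reference="control")
        mat = mds.unite(samples, design, min_coverage=10)
        res = mds.diff_test(mat)
        res["q_value"] = mds.adjust_fdr(res["p_value"].to_numpy())
        res = mds.call_differential(res)
        table = mds.chromosome_direction_counts(res)
        totals = table.sum(axis=1).reindex(["chr1", "chr2", "chr3"],
                                           fill_value=0)
        p = sps.chisquare(totals).pvalue
        rejections += p < 0.01
    assert rejections <= max(1, int(0.05 * n_seeds))
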