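"""F_ST definition against a brute-force oracle, outlier tails, SNP
classification, fixed differences, and haplotype-locus extraction."""

import numpy as np
import pandas as pd
import pytest

import poolcline as pc
from poolcline.differentiation import FstParams, fst_columns

from conftest import make_table


def brute_force_fst(c1, c2):
    """Independent reimplementation of the pi-based F_ST definition."""
    def het(c):
        c = np.asarray(c, dtype=float)
        m = c.sum()
        return m / (m - 1) * (1 - sum((x / m) ** 2 for x in c))

    pi_w = (het(c1) + het(c2)) / 2
    pi_t = het(np.asarray(c1) + np.asarray(c2))
    if pi_t <= 0:
        return 0.0
    return min(max((pi_t - pi_w) / pi_t, 0.0), 1.0)


class TestSnpFst:
    def test_identical_pools_zero(self):
        assert pc.snp_fst([15, 15, 0, 0], [15, 15, 0, 0]) == 0.0

    def test_fixed_difference_is_one(self):
        assert pc.snp_fst([30, 0, 0, 0], [0, 30, 0, 0]) == 1.0

    def test_hand_evaluated(self):
        assert pc.snp_fst([20, 10, 0, 0], [10, 20, 0, 0]) == pytest.approx(
            0.0958, abs=5e-4
        )

    def test_symmetry_and_self(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c1 = rng.integers(0, 40, 4)
            c2 = rng.integers(0, 40, 4)
            if c1.sum() == 0 or c2.sum() == 0:
                continue
            assert pc.snp_fst(c1, c2) == pytest.approx(pc.snp_fst(c2, c1))
            assert pc.snp_fst(c1, c1) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle_thousand_tables(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            c1 = rng.integers(0, 60, 4)
            c2 = rng.integers(0, 60, 4)
            if c1.sum() < 2 or c2.sum() < 2:
                continue
            assert pc.snp_fst(c1, c2) == pytest.approx(
                brute_force_fst(c1, c2), abs=1e-12
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pc.snp_fst([0, 0, 0, 0], [1, 2, 0, 0])


class TestPairwiseTable:
    def test_monomorphic_input_empty(self):
        t = make_table(
            [("sc1", i, "A", [[30, 0, 0, 0, 0, 0]] * 2) for i in range(1, 5)], 2
        )
        assert len(pc.pairwise_fst_table(t)) == 0

    def test_min_minor_count_filter(self):
        t = make_table(
            [
                ("sc1", 1, "A", [[27, 3, 0, 0, 0, 0], [30, 0, 0, 0, 0, 0]]),
                ("sc1", 2, "A", [[26, 4, 0, 0, 0, 0], [30, 0, 0, 0, 0, 0]]),
            ],
            2,
        )
        fst = pc.pairwise_fst_table(t, FstParams(min_minor_count=4))
        assert list(fst.position) == [2]

    def test_cluster_ordering(self, neutral_dataset):
        fst = pc.pairwise_fst_table(neutral_dataset.table)
        means = {c: fst[c].mean() for c in fst_columns(fst)}
        within_a = np.mean([means["fst_0_1"], means["fst_0_3"], means["fst_1_2"]])
        a_vs_c = np.mean([means[f"fst_{i}_5"] for i in range(4)])
        a_vs_adm = np.mean([means[f"fst_{i}_4"] for i in range(4)])
        assert a_vs_c > a_vs_adm > within_a

    def test_selected_loci_enriched_in_tail(self, gradient_dataset):
        ds = gradient_dataset
        fst = pc.pairwise_fst_table(ds.table)
        vals = fst[fst_columns(fst)].to_numpy().max(axis=1)
        _, out_idx = pc.empirical_outliers(vals, 0.995)
        sel = set(zip(ds.truth.scaffold[ds.truth.selected],
                      ds.truth.position[ds.truth.selected]))
        keys = list(zip(fst.scaffold, fst.position))
        is_sel = np.array([k in sel for k in keys])
        tail_frac = is_sel[out_idx].mean()
        genome_frac = is_sel.mean()
        assert tail_frac >= 5 * genome_frac


class TestFisherAndOutliers:
    def test_extreme_table(self):
        assert pc.fisher_allele_test([[4, 0], [0, 4]]) == pytest.approx(2 / 70)

    def test_balanced_table(self):
        assert pc.fisher_allele_test([[2, 2], [2, 2]]) == 1.0

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert pc.fisher_allele_test([[0, 0], [3, 4]]) == 1.0

    def test_bonferroni_fifteen_pairwise_tests(self):
        assert round(pc.bonferroni_threshold(0.05, 15), 3) == 0.003

    def test_quantile_tail_count(self):
        thresh, idx = pc.empirical_outliers(np.arange(1, 201), 0.975)
        assert thresh == pytest.approx(195.025)
        assert len(idx) == 5

    def test_constant_values_all_flagged(self):
        thresh, idx = pc.empirical_outliers(np.full(10, 0.7), 0.995)
        assert thresh == 0.7 and len(idx) == 10

    def test_saturated_distribution_inclusive_ties(self):
        vals = np.concatenate([np.random.default_rng(0).uniform(0, 0.9, 900),
                               np.ones(100)])
        thresh, idx = pc.empirical_outliers(vals, 0.995)
        assert thresh == 1.0
        assert len(idx) == 100  # every tie at the threshold flagged


class TestGeneSummary:
    def make_models(self):
        genes = pd.DataFrame(
            [
                dict(gene_id="g1", scaffold="sc1", strand="+", start=1000,
                     end=2000),
                dict(gene_id="g2", scaffold="sc1", strand="+", start=5000,
                     end=6000),
            ]
        )
        exons = {"g1": [(1000, 2000)], "g2": [(5000, 6000)]}
        return pc.GeneModels(genes, exons, {"g1": [], "g2": []})

    def test_mean_and_flag(self):
        fst = pd.DataFrame(
            dict(
                scaffold=["sc1"] * 4,
                position=[1100, 1200, 5100, 5200],
                major=list("AAAA"),
                minor=list("TTTT"),
                fst_0_1=[0.2, 0.4, 1.0, 1.0],
            )
        )
        per_gene, summary = pc.gene_fst_summary(fst, self.make_models())
        g1 = per_gene[per_gene.gene_id == "g1"].iloc[0]
        g2 = per_gene[per_gene.gene_id == "g2"].iloc[0]
        assert g1.score == pytest.approx(0.3)
        assert g2.score == pytest.approx(1.0)
        assert bool(g2.outlier)
        assert summary["n_genes_with_snps"] == 2


class TestClassification:
    def make_models(self):
        genes = pd.DataFrame(
            [
                dict(gene_id="g1", scaffold="sc1", strand="+", start=1000,
                     end=2000),
                dict(gene_id="g2", scaffold="sc1", strand="-", start=4000,
                     end=5000),
            ]
        )
        exons = {"g1": [(1000, 1400), (1600, 2000)], "g2": [(4000, 5000)]}
        cds = {"g1": [(1100, 1400)], "g2": []}
        return pc.GeneModels(genes, exons, cds)

    @pytest.mark.parametrize(
        "pos,top,sub,prom",
        [
            (1500, "genic", "intronic", False),
            (1200, "genic", "coding", False),
            (1050, "genic", "exonic", False),
            (500, "intergenic", "", True),     # 500 bp upstream of g1 (+)
            (250, "intergenic", "", False),    # 750 bp upstream: too far
            (5400, "intergenic", "", True),    # 400 bp upstream of g2 (-)
            (3000, "intergenic", "", False),
        ],
    )
    def test_assignments(self, pos, top, sub, prom):
        cls = pc.classify_snps(np.array(["sc1"]), np.array([pos]),
                               self.make_models())
        row = cls.iloc[0]
        assert (row.top, row.subclass, bool(row.promoter)) == (top, sub, prom)

    def test_partition_sums(self, gradient_dataset):
        ds = gradient_dataset
        cls = pc.classify_snps(ds.table.scaffold, ds.table.position,
                               ds.gene_models)
        summary = pc.classification_summary(cls)
        assert summary["GENIC"] + summary["INTERGENIC"] == summary["total"]
        assert summary["total"] == len(ds.table)


class TestFixedDifferences:
    def build(self, rows):
        full = np.zeros((len(rows), 6, 6), dtype=np.int64)
        full[:, :, :4] = np.array(rows)
        return pc.SiteCountsTable(
            np.array(["s"] * len(rows), dtype=object),
            np.arange(1, len(rows) + 1),
            np.array(["A"] * len(rows), dtype=object),
            full,
        )

    def test_fixed_and_noise_and_polymorphic(self):
        t = self.build(
            [
                [[30, 0, 0, 0]] * 4 + [[15, 15, 0, 0]] + [[0, 30, 0, 0]],
                [[29, 1, 0, 0]] * 4 + [[15, 15, 0, 0]] + [[0, 30, 0, 0]],
                [[20, 10, 0, 0]] * 4 + [[15, 15, 0, 0]] + [[0, 30, 0, 0]],
            ]
        )
        idx = pc.fixed_between_clusters(t, (0, 1, 2, 3), (5,), 4)
        assert idx.tolist() == [0, 1]

    def test_symmetric_in_clusters(self, neutral_dataset):
        t = neutral_dataset.table
        a = pc.fixed_between_clusters(t, (0, 1, 2, 3), (5,), 4)
        b = pc.fixed_between_clusters(t, (5,), (0, 1, 2, 3), 4)
        assert a.tolist() == b.tolist()

    def test_overlapping_clusters_rejected(self, neutral_dataset):
        with pytest.raises(ValueError):
            pc.fixed_between_clusters(neutral_dataset.table, (0, 1), (1, 2), 4)


class TestHaplotypeLoci:
    def test_full_extraction_manifest(self):
        cfg = pc.SimulationConfig(seed=5)
        reads, snps = pc.simulate_haplotype_reads(7, cfg)
        loci = pc.extract_haplotype_loci(reads, snps, seed=1)
        assert loci.manifest["n_loci"] == 7
        assert loci.manifest["n_sequences"] == 20 * 6 * 7
        for loc in loci.loci:
            assert 20 <= loc["end"] - loc["start"] < 90
            assert len(loc["snp_positions"]) >= 3
            for seqs in loc["haplotypes"].values():
                assert len(seqs) == 20
                assert all(len(s) == loc["end"] - loc["start"] for s in seqs)

    def test_one_locus_per_scaffold(self):
        cfg = pc.SimulationConfig(seed=5)
        reads, snps = pc.simulate_haplotype_reads(3, cfg)
        loci = pc.extract_haplotype_loci(reads, snps, seed=1)
        scafs = [l["scaffold"] for l in loci.loci]
        assert len(scafs) == len(set(scafs))

    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([100, 120], None),                  # only two SNPs
            ([100, 150, 195], None),             # span 96 >= 90
            ([100, 105, 110], None),             # span 11 < 20 bp
            ([100, 130, 160], (99, 160)),        # qualifies
        ],
    )
    def test_candidate_region_rules(self, positions, expected):
        from poolcline.differentiation import _candidate_region

        assert _candidate_region(np.array(positions)) == expected

    def test_undercovered_population_drops_locus(self):
        cfg = pc.SimulationConfig(seed=5)
        reads, snps = pc.simulate_haplotype_reads(2, cfg)
        reads = reads[~((reads.scaffold == "hap0001")
                        & (reads.population == "pop1"))]
        loci = pc.extract_haplotype_loci(reads, snps, seed=1)
        assert loci.manifest["n_loci"] == 1
        assert "hap0001" in loci.manifest["dropped"]
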