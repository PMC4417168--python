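"""RPKM, pre/post splitting, and the defect caller (Fisher + BH)."""

import numpy as np
import pandas as pd
import pytest

from intragenic_te import expression, synthetic_data, te_classify
from intragenic_te.expression import RegionCounts
from intragenic_te.intervals import GenomicInterval

from conftest import make_gene, make_te


class TestRpkm:
    def test_formula(self):
        rpkm, log2v = expression.compute_rpkm(10, 1000, 1_000_000)
        assert rpkm == pytest.approx(10.0)
        assert log2v == pytest.approx(np.log2(11))

    def test_zero_counts(self):
        assert expression.compute_rpkm(0, 500, 10**6) == (0.0, 0.0)

    def test_depth_scaling(self):
        r1, _ = expression.compute_rpkm(10, 1000, 10**6)
        r2, _ = expression.compute_rpkm(10, 1000, 2 * 10**6)
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            expression.compute_rpkm(10, 0, 10**6)


class TestGroupComparison:
    def test_planted_ordering_recovered(self, rng):
        n = 200
        high = np.log2(rng.lognormal(2.0, 1.0, n) + 1)
        low = np.log2(rng.lognormal(2.5, 1.0, n) + 1)
        none = np.log2(rng.lognormal(3.0, 1.0, n) + 1)
        out = expression.expression_group_comparison(
            {"high": high, "low": low, "none": none}
        ).set_index(["group_a", "group_b"])
        assert out.loc[("high", "none"), "p_value"] < 0.05
        assert out.loc[("high", "none"), "mean_a"] < out.loc[("high", "none"), "mean_b"]

    def test_identical_sets_p_near_one(self):
        x = np.arange(30.0)
        out = expression.expression_group_comparison({"a": x, "b": x})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            expression.expression_group_comparison({"a": [], "b": [1.0]})


class TestSplitPrePost:
    def _gene(self, strand):
        return make_gene(strand=strand)

    def _te_class(self):
        return te_classify.TEClassification("TE1", "intragenic", "intronic", "G1", 1.0, 100)

    def test_plus_strand(self):
        gene = self._gene("+")
        te = make_te(start=2400, end=2600)  # intron 2 (2301..2999)
        rc = expression.split_pre_post(gene, self._te_class(), [10, 20, 30, 40], te)
        assert (rc.pre_count, rc.post_count) == (30, 70)

    def test_minus_strand_reverses(self):
        gene = self._gene("-")
        te = make_te(start=2400, end=2600)
        rc = expression.split_pre_post(gene, self._te_class(), [10, 20, 30, 40], te)
        assert (rc.pre_count, rc.post_count) == (70, 30)

    def test_last_intron_zero_downstream(self):
        gene = self._gene("+")
        te = make_te(start=3500, end=3700)  # last intron
        rc = expression.split_pre_post(gene, self._te_class(), [10, 20, 30, 0], te)
        assert (rc.pre_count, rc.post_count) == (60, 0)

    def test_bookkeeping_identity(self):
        gene = self._gene("+")
        te = make_te(start=2400, end=2600)
        counts = [7, 13, 29, 31]
        rc = expression.split_pre_post(gene, self._te_class(), counts, te)
        assert rc.pre_count + rc.post_count == sum(counts)

    def test_te_outside_introns_errors(self):
        gene = self._gene("+")
        te = make_te(start=2100, end=2200)  # inside exon 2
        with pytest.raises(ValueError):
            expression.split_pre_post(gene, self._te_class(), [1, 2, 3, 4], te)


def region(gene_id, pre, post, genotype="wild-type"):
    return RegionCounts(gene_id, f"{gene_id}.te", genotype, pre, post)


class TestDefectTest:
    def test_strong_reduction_is_defect(self):
        pairs = [(region("G1", 100, 100), region("G1", 100, 10, "cmt3"))]
        res = expression.call_defects(pairs)[0]
        assert res.ratio_change == pytest.approx(0.1)
        assert res.label == "D"
        # Fisher p on [[100,100],[100,10]] matches stats_core (oracle-tested)
        from intragenic_te.stats_core import fisher_exact_2x2
        assert res.p_value == pytest.approx(
            fisher_exact_2x2([[100, 100], [100, 10]]).p_value
        )

    def test_identical_ratios_nd(self):
        pairs = [(region("G1", 50, 50), region("G1", 50, 50, "cmt3"))]
        res = expression.call_defects(pairs)[0]
        assert res.p_value == pytest.approx(1.0)
        assert res.label == "ND"

    @pytest.mark.parametrize(
        "wt,mut",
        [
            ((9, 100), (100, 100)),   # pre_wt below threshold
            ((100, 9), (100, 100)),   # post_wt below threshold
            ((100, 100), (9, 100)),   # pre_mut below threshold
        ],
    )
    def test_read_filters(self, wt, mut):
        pairs = [(region("G1", *wt), region("G1", *mut, "cmt3"))]
        assert expression.call_defects(pairs)[0].label == "filtered"

    def test_significant_increase_is_nd(self):
        """Directionality: strong upward post/pre change is not a defect."""
        pairs = [(region("G1", 100, 10), region("G1", 100, 100, "cmt3"))]
        res = expression.call_defects(pairs)[0]
        assert res.q_value <= 0.01 and res.label == "ND"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            RegionCounts("G", "T", "wt", -1, 5)

    def test_bh_across_genes(self):
        pairs = [
            (region(f"G{i}", 500, 500), region(f"G{i}", 500, 500 if i else 100, "cmt3"))
            for i in range(20)
        ]
        results = expression.call_defects(pairs)
        labels = [r.label for r in results]
        assert labels[0] == "D" and set(labels[1:]) == {"ND"}
        for r in results:
            assert r.q_value >= r.p_value - 1e-15


class TestNullAndPower:
    def test_null_defect_fraction_controlled(self):
        """Under identical wild-type/mutant ratios, BH keeps D labels <= 1%."""
        df = synthetic_data.simulate_null_region_counts(1500, rng=7)
        pairs = [
            (
                RegionCounts(r.gene_id, "te", "wild-type", r.pre_wt, r.post_wt),
                RegionCounts(r.gene_id, "te", "mut", r.pre_mut, r.post_mut),
            )
            for r in df.itertuples()
        ]
        results = expression.call_defects(pairs)
        tested = [r for r in results if r.label != "filtered"]
        frac_d = sum(r.label == "D" for r in tested) / len(tested)
        assert frac_d <= 0.01

    def test_power_at_fivefold_reduction(self, rng):
        """~500-read regions with a 5x downstream drop are almost always caught."""
        n = 200
        pairs = []
        for i in range(n):
            pre_wt, post_wt = rng.poisson(500), rng.poisson(500)
            pre_mut, post_mut = rng.poisson(500), rng.poisson(100)
            pairs.append(
                (
                    RegionCounts(f"G{i}", "te", "wild-type", pre_wt, post_wt),
                    RegionCounts(f"G{i}", "te", "mut", pre_mut, post_mut),
                )
            )
        results = expression.call_defects(pairs)
        frac_d = sum(r.label == "D" for r in results) / n
        assert frac_d >= 0.95


class TestAssociation:
    def _defects(self, n_d=50, n_nd=50):
        rows = []
        for i in range(n_d + n_nd):
            rows.append(
                {
                    "gene_id": f"G{i}", "te_id": f"T{i}", "genotype": "cmt3",
                    "label": "D" if i < n_d else "ND",
                }
            )
        return pd.DataFrame(rows)

    def test_planted_effect_recovered(self, rng):
        defects = self._defects()
        deltas = pd.DataFrame(
            {
                "te_id": defects["te_id"],
                "genotype": "cmt3",
                "abs_delta_CHG": np.where(
                    defects["label"] == "D",
                    -rng.uniform(0.2, 0.4, len(defects)),
                    -rng.uniform(0.05, 0.15, len(defects)),
                ),
            }
        )
        out = expression.defect_methylation_association(defects, deltas)
        assert len(out) == 1
        assert out["p_value"].iloc[0] < 0.05
        assert out["mean_delta_D"].iloc[0] < out["mean_delta_ND"].iloc[0]

    def test_shuffled_labels_null_calibration(self, rng):
        """With labels random, association p-values are roughly uniform."""
        from scipy import stats as sps

        ps = []
        for _ in range(200):
            defects = self._defects(25, 25).sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
            deltas = pd.DataFrame(
                {
                    "te_id": defects["te_id"],
                    "genotype": "cmt3",
                    "abs_delta_CHG": -rng.uniform(0, 0.4, len(defects)),
                }
            )
            ps.append(
                expression.defect_methylation_association(defects, deltas)["p_value"].iloc[0]
            )
        assert sps.kstest(ps, "uniform").statistic < 0.1

    def test_dedup_keeps_single_record_per_gene(self):
        defects = pd.DataFrame(
            {
                "gene_id": ["G1"] * 3, "te_id": ["T1", "T2", "T3"],
                "genotype": "cmt3", "label": ["D", "ND", "D"],
            }
        )
        out = expression.dedup_representative_te(
            defects, te_lengths={"T1": 100, "T2": 500, "T3": 500},
            wt_chg={"T2": 0.1, "T3": 0.4},
        )
        assert out["te_id"].tolist() == ["T3"]  # longest, tie -> most methylated


class TestTeExpression:
    def test_pseudocount_fold_change(self):
        out = expression.te_expression(
            te_counts={"wild-type": {"T1": 0}, "met1": {"T1": 0}},
            te_lengths={"T1": 500},
            library_sizes={"wild-type": 10**6, "met1": 10**6},
        )
        assert out["fold_met1"].iloc[0] == pytest.approx(1.0)

    def test_planted_activation_recovered(self, rng):
        depth = 10**6
        length = 2000
        wt_counts = int(rng.poisson(2000))
        mut_counts = int(rng.poisson(20000))
        out = expression.te_expression(
            te_counts={"wild-type": {"T1": wt_counts}, "met1": {"T1": mut_counts}},
            te_lengths={"T1": length},
            library_sizes={"wild-type": depth, "met1": depth},
        )
        fold = out["fold_met1"].iloc[0]
        assert fold == pytest.approx(
            (mut_counts / 2 + 1) / (wt_counts / 2 + 1), rel=1e-12
        )
        assert 10 * 0.75 < fold < 10 * 1.35

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            expression.te_expression(
                te_counts={"wild-type": {"T1": 5}},
                te_lengths={"T1": 0},
                library_sizes={"wild-type": 10**6},
            )


def test_planted_defects_recovered_from_bundle(sim_dir, reconciled_te_set, filtered_genes):
    """End-to-end: simulated counts -> pre/post split -> Fisher+BH labels."""
    out, cfg, truth = sim_dir
    cls = te_classify.classify_all(reconciled_te_set, filtered_genes)
    gene_by_id = {g.gene_id: g for g in filtered_genes}
    te_by_id = {t.te_id: t for t in reconciled_te_set}
    counts = {
        p.stem[len("counts_"):]: pd.read_csv(p, sep="\t")
        for p in sorted(out.glob("counts_*.tsv"))
    }
    genotype = "cmt3"
    pairs = []
    for c in cls:
        if c.subcategory != "intronic":
            continue
        gene = gene_by_id[c.host_gene_id]
        idx = expression.te_containing_intron_index(gene, te_by_id[c.te_id].interval)
        def exon_counts(gt):
            sub = counts[gt][counts[gt]["gene_id"] == gene.gene_id]
            return sub.sort_values("exon_index")["count"].tolist()
        pairs.append(
            (
                expression.split_pre_post(gene, c, exon_counts("wild-type"),
                                          genotype="wild-type", intron_index=idx),
                expression.split_pre_post(gene, c, exon_counts(genotype),
                                          genotype=genotype, intron_index=idx),
            )
        )
    results = expression.call_defects(pairs)
    planted = truth.defects[truth.defects["genotype"] == genotype].set_index("te_id")
    tested = [r for r in results if r.label != "filtered"]
    assert tested, "no testable intronic-TE genes in the bundle"
    agree = [r.label == ("D" if planted.loc[r.te_id, "is_defect"] else "ND") for r in tested]
    assert np.mean(agree) >= 0.8
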