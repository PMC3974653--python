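"""Cross-species meta-analysis: z-scoring, merge, fold filter, correlations."""

import numpy as np
import pandas as pd
import pytest

from pheoscreen import simulate
from pheoscreen.meta import (
    DrugTargetMap,
    ExpressionMatrix,
    drug_target_correlation,
    fold_change_filter,
    merge_common_genes,
    overall_correlation,
    replicate_correlation,
    zscore_genes,
)


def em(data, genes, samples, **kw):
    kw.setdefault("normalized", "zscore")
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples), **kw)


class TestZscore:
    def test_closed_form_row(self):
        m = em([[1.0, 2.0, 3.0]], ["G1"], ["s1", "s2", "s3"], normalized="raw")
        z = zscore_genes(m)
        assert np.allclose(z.values.loc["G1"], [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert z.normalized == "zscore"

    def test_rows_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        m = em(rng.normal(2, 5, (30, 6)), [f"G{i}" for i in range(30)],
               [f"s{j}" for j in range(6)], normalized="raw")
        z = zscore_genes(m).values
        assert np.all(np.abs(z.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(z.std(axis=1, ddof=0) - 1) < 1e-10)

    def test_constant_row_zeroed_and_flagged(self):
        m = em([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], ["FLAT", "G"],
               ["a", "b", "c"], normalized="raw")
        z = zscore_genes(m)
        assert z.zero_variance_genes == ["FLAT"]
        assert (z.values.loc["FLAT"] == 0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = em(rng.normal(0, 3, (10, 5)), [f"G{i}" for i in range(10)],
               [f"s{j}" for j in range(5)], normalized="raw")
        once = zscore_genes(m)
        twice = zscore_genes(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_single_sample_rejected(self):
        m = em([[1.0]], ["G"], ["s1"], normalized="raw")
        with pytest.raises(ValueError, match=">=2 samples"):
            zscore_genes(m)

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            em([[1, 2], [3, 4]], ["G", "G"], ["a", "b"])

    def test_missing_values_dropped_at_load(self):
        m = em([[1.0, np.nan], [3.0, 4.0]], ["BAD", "OK"], ["a", "b"])
        assert list(m.genes) == ["OK"]


class TestMerge:
    def test_identical_gene_sets(self):
        a = em(np.eye(4), list("ABCD"), ["a1", "a2", "a3", "a4"])
        b = em(np.eye(4), list("ABCD"), ["b1", "b2", "b3", "b4"])
        merged = merge_common_genes(a, b)
        assert len(merged.common_genes) == 4
        assert list(merged.values.columns) == merged.samples_a + merged.samples_b

    def test_case_insensitive_symbol_namespace(self):
        a = em([[1, 2], [3, 4]], ["Tp53", "Myc"], ["a1", "a2"])
        b = em([[1, 2], [3, 4]], ["TP53", "BRCA1"], ["b1", "b2"])
        merged = merge_common_genes(a, b)
        assert list(merged.common_genes) == ["TP53"]

    def test_generator_contract_1753_common(self):
        a, b, truth = simulate.gen_expression_pair(1753, rho=0.8, seed=0,
                                                   private_frac=0.15)
        # private genes belong to one dataset only, so the overlap is exactly
        # the planted shared set
        assert len(a.genes) == len(b.genes) == 1753 + round(0.15 * 1753)
        merged = merge_common_genes(a, b)
        assert len(merged.common_genes) == 1753
        restricted = merge_common_genes(a, b, restrict_to=truth["gene"])
        assert len(restricted.common_genes) == 1753

    def test_disjoint_sets_error(self):
        a = em([[1, 2]], ["X"], ["a1", "a2"])
        b = em([[1, 2]], ["Y"], ["b1", "b2"])
        with pytest.raises(ValueError, match="no common genes"):
            merge_common_genes(a, b)

    def test_raw_matrix_rejected(self):
        a = em([[1, 2]], ["X"], ["a1", "a2"], normalized="raw")
        b = em([[1, 2]], ["X"], ["b1", "b2"])
        with pytest.raises(ValueError, match="not scaled"):
            merge_common_genes(a, b)

    def test_commutative_in_gene_dimension(self):
        a, b, _ = simulate.gen_expression_pair(60, rho=0.5, seed=1,
                                               private_frac=0.3)
        g1 = set(merge_common_genes(a, b).common_genes)
        g2 = set(merge_common_genes(b, a).common_genes)
        assert g1 == g2

    def test_ortholog_map_override(self):
        a = em([[1, 2]], ["Trp53"], ["a1", "a2"])
        b = em([[1, 2]], ["TP53"], ["b1", "b2"])
        with pytest.raises(ValueError):
            merge_common_genes(a, b)
        merged = merge_common_genes(a, b, ortholog_map={"Trp53": "TP53"})
        assert list(merged.common_genes) == ["TP53"]


class TestFoldChangeFilter:
    def build_merged(self, deltas):
        genes = [f"G{i}" for i in range(len(deltas))]
        a = em([[d / 2, d / 2] for d in deltas], genes, ["a1", "a2"])
        b = em([[-d / 2, -d / 2] for d in deltas], genes, ["b1", "b2"])
        return merge_common_genes(a, b)

    def test_identical_means_kept(self):
        merged = self.build_merged([0.0, 0.0])
        assert len(fold_change_filter(merged)) == 2

    def test_planted_4fold_gene_removed(self):
        merged = self.build_merged([0.0, 2.0])  # |delta|=2 = log2(4)
        assert fold_change_filter(merged, 2.0) == ["G0"]

    def test_enumerated_toy_counts(self):
        # 10 genes, 3 planted at >=2-fold -> 7 survivors
        deltas = [0.1, 0.2, 0.0, 1.5, 0.3, 2.5, 0.05, 1.01, 0.9, 0.4]
        merged = self.build_merged(deltas)
        assert len(fold_change_filter(merged, 2.0)) == 7

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        merged = self.build_merged(rng.uniform(0, 3, 40).tolist())
        small = set(fold_change_filter(merged, 1.5))
        large = set(fold_change_filter(merged, 4.0))
        assert small <= large

    def test_threshold_below_one_rejected(self):
        merged = self.build_merged([0.0])
        with pytest.raises(ValueError, match="> 1"):
            fold_change_filter(merged, 1.0)


class TestDrugTargetCorrelation:
    def test_identical_profiles_all_r_one(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(30)]
        vals = rng.normal(0, 1, (30, 3))
        a = em(vals, genes, ["a1", "a2", "a3"])
        b = em(vals + rng.normal(0, 1e-9, (30, 3)), genes, ["b1", "b2", "b3"])
        merged = merge_common_genes(a, b)
        dtmap = DrugTargetMap({"d1": set(genes[:10]), "d2": set(genes[5:25])})
        table, overall = drug_target_correlation(merged, dtmap)
        assert np.allclose(table["pearson_r"], 1.0, atol=1e-6)
        assert overall == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelated_drug_detected(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(40)]
        base = rng.normal(0, 1, 40)
        va = np.tile(base[:, None], (1, 2))
        vb = base.copy()
        vb[:10] = -vb[:10]  # first drug's targets flipped
        vb = np.tile(vb[:, None], (1, 2))
        merged = merge_common_genes(em(va, genes, ["a1", "a2"]),
                                    em(vb, genes, ["b1", "b2"]))
        dtmap = DrugTargetMap({"flipped": set(genes[:10]),
                               "normal": set(genes[10:])})
        table, _ = drug_target_correlation(merged, dtmap)
        t = table.set_index("drug")
        assert t.loc["flipped", "pearson_r"] < 0
        assert t.loc["normal", "pearson_r"] > 0.99

    def test_generator_contract_mean_r(self):
        a, b, truth = simulate.gen_expression_pair(800, rho=0.8, seed=6)
        merged = merge_common_genes(a, b)
        dtmap_df = simulate.gen_drug_target_map(22, list(truth["gene"]), seed=7)
        table, overall = drug_target_correlation(
            merged, DrugTargetMap.from_frame(dtmap_df))
        assert overall == pytest.approx(0.8, abs=0.05)

    def test_under_three_targets_flagged_undefined(self):
        a, b, truth = simulate.gen_expression_pair(20, rho=0.5, seed=8)
        merged = merge_common_genes(a, b)
        dtmap = DrugTargetMap({"tiny": {truth["gene"][0], truth["gene"][1]},
                               "ok": set(truth["gene"][:10])})
        table, overall = drug_target_correlation(merged, dtmap)
        t = table.set_index("drug")
        assert not t.loc["tiny", "defined"]
        assert np.isnan(t.loc["tiny", "pearson_r"])
        assert np.isfinite(overall)

    def test_sample_order_invariance(self):
        a, b, _ = simulate.gen_expression_pair(50, rho=0.6, seed=9)
        merged1 = merge_common_genes(a, b)
        b2 = ExpressionMatrix(b.values[b.values.columns[::-1]],
                              species=b.species, normalized=b.normalized)
        merged2 = merge_common_genes(a, b2)
        r1 = overall_correlation(merged1)
        r2 = overall_correlation(merged2)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert -1.0 <= r1 <= 1.0

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="empty target set"):
            DrugTargetMap({"d": set()})


class TestReplicateQC:
    def test_high_replicate_correlation_report(self):
        a, _, _ = simulate.gen_expression_pair(500, rho=0.8, seed=10)
        corr = replicate_correlation(a)
        off = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert off.min() > 0.9
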