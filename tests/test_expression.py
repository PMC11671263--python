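"""TPM, size factors, NB differential expression, clustering, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isocurl.expression import (DEResult, SampleDesign, call_degs,
                                cluster_expression, compute_tpm, enrich_terms,
                                nb_de_test, pca_samples, size_factors)
from isocurl.synthetic import SimConfig, generate_count_matrix


def make_design(n_stages=4, n_reps=3):
    rows = [(f"{organ}_s{s}_r{r}", organ, s, r)
            for organ in ("sepal", "petal")
            for s in range(1, n_stages + 1) for r in range(1, n_reps + 1)]
    return SampleDesign(pd.DataFrame(rows, columns=["sample", "organ", "stage",
                                                    "replicate"]).set_index("sample"))


class TestTPM:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        tpm = compute_tpm(counts, lengths)
        assert tpm["s1"].tolist() == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_symmetry_equal_counts_and_lengths(self):
        counts = pd.DataFrame({"s1": [7, 7, 7, 7]})
        tpm = compute_tpm(counts, pd.Series([500.0] * 4))
        assert tpm["s1"].tolist() == pytest.approx([250000.0] * 4)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (50, 6)))
        counts.iloc[0] += 1  # avoid an all-zero sample
        tpm = compute_tpm(counts, pd.Series(rng.integers(200, 3000, 50).astype(float)))
        assert tpm.sum(axis=0).tolist() == pytest.approx([1e6] * 6)

    def test_scaling_invariance(self, rng):
        counts = pd.DataFrame({"s1": rng.integers(1, 100, 30)})
        lengths = pd.Series(rng.integers(100, 2000, 30).astype(float))
        assert np.allclose(compute_tpm(counts, lengths),
                           compute_tpm(counts * 7, lengths))

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            compute_tpm(counts, pd.Series([100.0, 100.0]))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 200, 100)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert size_factors(counts).tolist() == pytest.approx([1.0] * 4)

    def test_doubled_library_recovered(self, rng):
        col = rng.integers(5, 500, 500)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0, rel=0.01)

    def test_single_sample_unit_factor(self):
        assert size_factors(pd.DataFrame({"s": [3, 5]})).tolist() == [1.0]

    def test_no_common_nonzero_gene_rejected(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.raises(ValueError, match="filter"):
            size_factors(counts)


class TestNBDETest:
    def test_flat_gene_is_ns(self):
        genes = [f"g{i}" for i in range(40)]
        counts = pd.DataFrame(
            {s: [50] * 40 for s in make_design().table.index}, index=genes)
        de = nb_de_test(counts, make_design())
        assert (de.table["log2fc"] == 0).all()
        assert (de.table["direction"] == "ns").all()

    def test_all_zero_gene_excluded(self, rng):
        design = make_design()
        counts = pd.DataFrame(rng.integers(1, 100, (20, 24)),
                              index=[f"g{i}" for i in range(20)],
                              columns=design.table.index)
        counts.loc["g7"] = 0
        de = nb_de_test(counts, design)
        assert de.excluded == ["g7"] and "g7" not in de.table.index

    def test_null_type_one_error_calibrated(self):
        cfg = SimConfig(seed=31, n_genes=2000, frac_up=0.0, frac_down=0.0)
        counts, design, _ = generate_count_matrix(cfg)
        de = nb_de_test(counts, SampleDesign(design))
        assert (de.table["p_value"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_planted_fold_changes_recovered(self):
        cfg = SimConfig(seed=32, n_genes=1000, frac_up=0.05, frac_down=0.05)
        counts, design, truth = generate_count_matrix(cfg)
        de = nb_de_test(counts, SampleDesign(design))
        planted = {d["gene_id"]: d["direction"] for d in truth.de_genes}
        called = de.table[de.table["padj"] < 0.05]
        recall = len(set(planted) & set(called.index)) / len(planted)
        assert recall >= 0.9
        for gid, direction in planted.items():
            if gid in called.index:
                sign = 1 if direction == "up" else -1
                assert sign * called.loc[gid, "log2fc"] > 0

    def test_insufficient_replication_rejected(self):
        design = SampleDesign(pd.DataFrame(
            {"organ": ["sepal", "petal"], "stage": [1, 1], "replicate": [1, 1]},
            index=["a", "b"]))
        counts = pd.DataFrame({"a": [5], "b": [5]})
        with pytest.raises(ValueError, match="replicates"):
            nb_de_test(counts, design)


class TestCallDegs:
    def make_result(self, n_up, n_down, n_ns=100):
        n = n_up + n_down + n_ns
        lfc = np.concatenate([np.full(n_up, 2.0), np.full(n_down, -2.0),
                              np.zeros(n_ns)])
        padj = np.concatenate([np.full(n_up + n_down, 1e-4), np.ones(n_ns)])
        table = pd.DataFrame({"base_mean": 100.0, "log2fc": lfc,
                              "p_value": padj, "padj": padj,
                              "direction": "ns"},
                             index=[f"g{i}" for i in range(n)])
        return DEResult(table, [])

    def test_observed_up_down_split_percentages(self):
        degs, summary = call_degs(self.make_result(598, 223))
        assert (summary.n_up, summary.n_down) == (598, 223)
        assert summary.up_pct == 72.8 and summary.down_pct == 27.2

    def test_empty_deg_set(self):
        degs, summary = call_degs(self.make_result(0, 0))
        assert len(degs) == 0 and summary.up_pct == 0.0

    def test_thresholds_respected(self):
        result = self.make_result(10, 0)
        result.table.loc["g0", "log2fc"] = 0.5  # below |lfc| >= 1
        degs, _ = call_degs(result)
        assert "g0" not in degs.index


class TestClusterExpression:
    def test_planted_stage_patterns_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        patterns = np.array([[10, 10, 0, 0], [0, 0, 10, 10],
                             [10, 0, 10, 0], [0, 10, 0, 10]], float)
        rows, labels = [], []
        for k, pat in enumerate(patterns):
            for _ in range(50):
                rows.append(np.repeat(pat, 3) + rng.normal(0, 0.3, 12))
            labels += [k] * 50
        tpm = pd.DataFrame(np.maximum(np.array(rows), 0) * 100)
        got = cluster_expression(tpm, k=4)
        assert adjusted_rand_score(labels, got) >= 0.95

    def test_duplicate_rows_share_label(self, rng):
        base = rng.random((6, 8)) * 100
        tpm = pd.DataFrame(np.vstack([base, base[0]]))
        labels = cluster_expression(tpm, k=3)
        assert labels.iloc[0] == labels.iloc[6]

    def test_k_larger_than_gene_count(self):
        with pytest.raises(ValueError):
            cluster_expression(pd.DataFrame(np.ones((3, 4))), k=4)

    def test_constant_row_warns(self, rng):
        tpm = pd.DataFrame(np.vstack([np.full(6, 5.0), rng.random((5, 6))]))
        with pytest.warns(UserWarning, match="constant"):
            cluster_expression(tpm, k=2)


class TestPCA:
    def test_duplicated_sample_identical_coordinates(self, rng):
        x = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        x["e"] = x["a"]
        coords, _ = pca_samples(x)
        assert np.allclose(coords.loc["a"], coords.loc["e"])

    def test_variance_fractions_sum_to_one(self, rng):
        _, var_frac = pca_samples(pd.DataFrame(rng.random((40, 6))))
        assert var_frac.sum() == pytest.approx(1.0)

    def test_two_groups_separate_on_pc1(self, rng):
        a = rng.normal(0, 0.1, (50, 5))
        b = rng.normal(3, 0.1, (50, 5))
        x = pd.DataFrame(np.hstack([a, b]),
                         columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])
        coords, var_frac = pca_samples(x)
        pc1_a = coords.loc[[f"a{i}" for i in range(5)], "PC1"]
        pc1_b = coords.loc[[f"b{i}" for i in range(5)], "PC1"]
        assert max(pc1_a) < min(pc1_b) or min(pc1_a) > max(pc1_b)
        assert var_frac[0] > 0.9


def exact_hypergeom_p(overlap, universe, term_size, deg_size):
    """Oracle: exhaustive tail sum with exact binomial coefficients."""
    total = math.comb(universe, deg_size)
    tail = sum(math.comb(term_size, j) * math.comb(universe - term_size, deg_size - j)
               for j in range(overlap, min(term_size, deg_size) + 1))
    return tail / total


class TestEnrichment:
    def test_perfect_overlap_exact_probability(self):
        universe = [f"g{i}" for i in range(20)]
        term2gene = pd.DataFrame({"term": ["T1"] * 5, "gene": universe[:5]})
        table = enrich_terms(universe[:5], universe, term2gene)
        assert table.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5))

    def test_term_equal_to_universe(self):
        universe = [f"g{i}" for i in range(10)]
        term2gene = pd.DataFrame({"term": ["ALL"] * 10, "gene": universe})
        table = enrich_terms(universe[:3], universe, term2gene)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_small_universes(self, rng):
        for _ in range(25):
            m = int(rng.integers(8, 26))
            universe = [f"g{i}" for i in range(m)]
            term_size = int(rng.integers(1, m + 1))
            deg_size = int(rng.integers(1, m + 1))
            term = list(rng.choice(universe, term_size, replace=False))
            degs = list(rng.choice(universe, deg_size, replace=False))
            table = enrich_terms(degs, universe,
                                 pd.DataFrame({"t": ["T"] * term_size, "g": term}))
            overlap = len(set(term) & set(degs))
            if overlap:
                assert table.loc[0, "p"] == pytest.approx(
                    exact_hypergeom_p(overlap, m, term_size, deg_size))
            else:
                assert table.loc[0, "p"] == 1.0

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrich_terms(["x"], ["a", "b"], pd.DataFrame({"t": ["T"], "g": ["a"]}))

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        padj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert padj.tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_invariants_on_random_p_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 60)))
            p[: len(p) // 3] = p[0]  # force ties
            padj = multipletests(p, method="fdr_bh")[1]
            assert (padj >= p - 1e-12).all() and (padj <= 1).all()
            order = np.argsort(p)
            assert (np.diff(padj[order]) >= -1e-12).all()
            assert len({round(v, 12) for v in padj[p == p[0]]}) == 1
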