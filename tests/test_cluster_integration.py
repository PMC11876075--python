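from math import comb

import numpy as np
import pandas as pd
import pytest

from ridgemotif import (
    EnrichmentQuery,
    cluster_fc_correlation,
    filter_genes,
    geneset_shift_test,
    hypergeom_enrichment,
    kmeans_clusters,
    module_score,
    subset_score_matrix,
    zscore_rows,
)
from ridgemotif.cluster_integration import GeneCluster
from ridgemotif.io_formats import DifferentialTable, ExpressionTable


def make_expr(rows, samples=None):
    samples = samples or [f"{p}_r{r}" for p in ("neg", "recent", "stable") for r in (1, 2, 3)]
    df = pd.DataFrame(rows, columns=samples)
    return ExpressionTable(values=df, populations={s: s.rsplit("_", 1)[0] for s in samples})


class TestFilterGenes:
    def test_floor_segment_and_zero_rules(self):
        rows = {
            "Cd8a": [2.0] * 9,
            "Above": [2.1] * 9,
            "Below": [1.9] * 9,
            "Trbv13-1": [50.0] * 9,
            "Ighv1-2": [50.0] * 9,
            "MostlyZero": [18.0] * 4 + [0.0] * 5,  # zeros in 5 of 9: majority
            "SomeZero": [4.5] * 5 + [0.0] * 4,  # zeros in 4 of 9: kept
        }
        df = pd.DataFrame(rows).T
        df.columns = [f"{p}_r{r}" for p in ("neg", "recent", "stable") for r in (1, 2, 3)]
        expr = ExpressionTable(values=df, populations={c: c.rsplit("_", 1)[0] for c in df.columns})
        kept = filter_genes(expr)
        assert set(kept) == {"Cd8a", "Above", "SomeZero"}

    def test_missing_floor_gene_errors(self, expr_three_pops):
        with pytest.raises(ValueError, match="floor gene"):
            filter_genes(expr_three_pops, floor_gene="NotThere")


class TestKmeans:
    def test_two_separated_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 0.1, size=(20, 5))
        b = rng.normal(8, 0.1, size=(25, 5))
        z = pd.DataFrame(np.vstack([a, b]),
                         index=[f"g{i}" for i in range(45)])
        clusters = kmeans_clusters(z, k=2, seed=0)
        sets = [set(c.genes) for c in clusters]
        assert {frozenset(s) for s in sets} == {
            frozenset(f"g{i}" for i in range(20)),
            frozenset(f"g{i}" for i in range(20, 45)),
        }
        # labels ordered by descending size
        assert len(clusters[0].genes) >= len(clusters[1].genes)

    def test_k_equals_n_gives_singletons(self, rng):
        z = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        clusters = kmeans_clusters(z, k=5, seed=0, n_init=10)
        assert sorted(len(c.genes) for c in clusters) == [1] * 5

    def test_k_larger_than_n_errors(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_clusters(z, k=7)

    def test_planted_archetypes_recovered(self, rng):
        """Seven well-separated planted profiles: >= 95% label agreement
        after optimal (Hungarian) matching."""
        from scipy.optimize import linear_sum_assignment

        centers = rng.normal(0, 4, size=(7, 9))
        genes, truth, rows = [], [], []
        for c in range(7):
            for i in range(40):
                genes.append(f"g{c}_{i}")
                truth.append(c)
                rows.append(centers[c] + rng.normal(0, 1.0, 9))
        z = pd.DataFrame(rows, index=genes)
        clusters = kmeans_clusters(z, k=7, seed=0)
        label = {g: ci for ci, c in enumerate(clusters) for g in c.genes}
        pred = np.array([label[g] for g in genes])
        truth = np.array(truth)
        conf = np.zeros((7, 7), dtype=int)
        for t, p in zip(truth, pred):
            conf[t, p] += 1
        r, col = linear_sum_assignment(-conf)
        agreement = conf[r, col].sum() / len(genes)
        assert agreement >= 0.95


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        counts = pd.DataFrame(np.ones((10, 40)),
                              columns=[f"g{i}" for i in range(40)])
        s = module_score(counts, ["g0", "g1", "g2"], seed=0)
        np.testing.assert_allclose(s.values, 0.0)

    def test_program_cells_score_higher(self, rng):
        n_cells, n_genes = 200, 120
        base = rng.lognormal(0, 0.3, size=(n_cells, n_genes))
        program = [f"g{i}" for i in range(10)]
        positive = np.arange(n_cells) < 100
        base[positive, :10] *= 3.0
        counts = pd.DataFrame(np.log1p(base), columns=[f"g{i}" for i in range(n_genes)])
        s = module_score(counts, program, seed=0)
        assert s[positive].mean() > s[~positive].mean()

    def test_gene_set_outside_matrix_errors(self, rng):
        counts = pd.DataFrame(rng.random((5, 10)), columns=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="overlap"):
            module_score(counts, ["nope1", "nope2"])

    def test_invariant_to_absent_gene_padding(self, rng):
        counts = pd.DataFrame(rng.random((30, 50)), columns=[f"g{i}" for i in range(50)])
        s1 = module_score(counts, ["g1", "g2", "g3"], seed=42)
        s2 = module_score(counts, ["g1", "g2", "g3", "absentA", "absentB"], seed=42)
        np.testing.assert_allclose(s1.values, s2.values)


class TestSubsetScoreMatrix:
    def test_z_formula_on_three_subsets(self):
        scores = pd.DataFrame({"bI": [1.0] * 30 + [2.0] * 30 + [3.0] * 30})
        labels = pd.Series(["s1"] * 30 + ["s2"] * 30 + ["s3"] * 30,
                           index=scores.index)
        table = subset_score_matrix(scores, labels)
        np.testing.assert_allclose(
            table.zscores["bI"].values, [-1.2247, 0.0, 1.2247], atol=1e-3
        )
        assert table.zscores["bI"].mean() == pytest.approx(0.0, abs=1e-12)
        assert table.zscores["bI"].std(ddof=0) == pytest.approx(1.0)

    def test_small_subsets_excluded(self):
        scores = pd.DataFrame({"bI": [1.0] * 25 + [2.0] * 25 + [9.0] * 5})
        labels = pd.Series(["s1"] * 25 + ["s2"] * 25 + ["tiny"] * 5, index=scores.index)
        table = subset_score_matrix(scores, labels, min_cells=20)
        assert table.excluded_subsets == ["tiny"]
        assert list(table.means.index) == ["s1", "s2"]

    def test_degenerate_equal_means_reported_as_zero(self):
        scores = pd.DataFrame({"bI": [1.0] * 60})
        labels = pd.Series(["s1"] * 30 + ["s2"] * 30, index=scores.index)
        table = subset_score_matrix(scores, labels)
        np.testing.assert_allclose(table.zscores["bI"].values, 0.0)


def oracle_hypergeom_tail(q, m, n, k):
    denom = comb(m + n, k)
    return sum(comb(m, x) * comb(n, k - x) for x in range(q, min(m, k) + 1)) / denom


class TestHypergeom:
    def test_q_zero_is_certain(self):
        assert hypergeom_enrichment(EnrichmentQuery(0, 10, 20, 5)) == pytest.approx(1.0)

    def test_worked_value_one_over_252(self):
        p = hypergeom_enrichment(EnrichmentQuery(5, 5, 5, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_forced_overlap(self):
        assert hypergeom_enrichment(EnrichmentQuery(3, 3, 0, 3)) == pytest.approx(1.0)

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(6, 5, 5, 5)

    def test_matches_enumeration_small_universes(self):
        for m in range(1, 8):
            for n in range(0, 8):
                for k in range(0, m + n + 1):
                    for q in range(0, min(m, k) + 1):
                        got = hypergeom_enrichment(EnrichmentQuery(q, m, n, k))
                        assert got == pytest.approx(oracle_hypergeom_tail(q, m, n, k),
                                                    rel=1e-10, abs=1e-12)


class TestGenesetShift:
    def test_set_equals_background_gives_zero_d(self, rng):
        fc = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        d, p = geneset_shift_test(fc, list(fc.index))
        assert d == pytest.approx(0.0)

    def test_shifted_set_is_highly_significant(self, rng):
        fc = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        fc.iloc[:100] += 1.0  # one-sd shift of a 100-gene set
        d, p = geneset_shift_test(fc, [f"g{i}" for i in range(100)])
        assert p < 1e-6

    def test_degenerate_sets_rejected(self, rng):
        fc = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            geneset_shift_test(fc, ["g0"])


class TestClusterFcCorrelation:
    def _tables(self, gene_fc, peak_fc, links):
        de = DifferentialTable(
            pd.DataFrame({"log2fc_svn": gene_fc, "padj_svn": 0.01}), ["svn"]
        )
        da = DifferentialTable(
            pd.DataFrame({"log2fc_svn": peak_fc, "padj_svn": 0.01}), ["svn"]
        )
        return de, da, links

    def test_identical_fc_gives_r_one(self):
        gene_fc = pd.Series({"gA": 1.0, "gB": -0.5, "gC": 2.0})
        peak_fc = pd.Series({"p1": 1.0, "p2": -0.5, "p3": 2.0})
        links = {"p1": "gA", "p2": "gB", "p3": "gC"}
        de, da, links = self._tables(gene_fc, peak_fc, links)
        clusters = [GeneCluster("bI", ["gA", "gB", "gC"], pd.Series(dtype=float))]
        r = cluster_fc_correlation(de, da, links, clusters, "svn")
        assert r["bI"] == pytest.approx(1.0)

    def test_independent_noise_gives_small_r(self, rng):
        genes = [f"g{i}" for i in range(2000)]
        peaks = [f"p{i}" for i in range(2000)]
        de, da, links = self._tables(
            pd.Series(rng.normal(size=2000), index=genes),
            pd.Series(rng.normal(size=2000), index=peaks),
            dict(zip(peaks, genes)),
        )
        clusters = [GeneCluster("bI", genes, pd.Series(dtype=float))]
        r = cluster_fc_correlation(de, da, links, clusters, "svn")
        assert abs(r["bI"]) < 0.1

    def test_two_pairs_is_an_error(self):
        de, da, links = self._tables(
            pd.Series({"gA": 1.0, "gB": 2.0}),
            pd.Series({"p1": 1.0, "p2": 2.0}),
            {"p1": "gA", "p2": "gB"},
        )
        clusters = [GeneCluster("bI", ["gA", "gB"], pd.Series(dtype=float))]
        with pytest.raises(ValueError, match="pairs"):
            cluster_fc_correlation(de, da, links, clusters, "svn")


def test_zscore_rows_handles_constant_rows():
    df = pd.DataFrame({"a": [1.0, 5.0], "b": [1.0, 7.0], "c": [1.0, 9.0]},
                      index=["flat", "varying"])
    z = zscore_rows(df)
    np.testing.assert_allclose(z.loc["flat"].values, 0.0)
    assert z.loc["varying"].mean() == pytest.approx(0.0, abs=1e-12)
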