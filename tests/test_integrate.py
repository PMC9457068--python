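"""Enrichment, association and correlation statistics vs direct oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subtadscope.domains import BoundarySet
from subtadscope.integrate import (
    _exact_spearman_p,
    boundary_expression_association,
    correlation_ranking,
    delta_delta_correlation,
    geneset_enrichment_vs_constant,
    oe_boundary_enrichment,
)
from subtadscope.io_model import FeatureSet, GenomicInterval

from test_domains import adjacency_table, make_set


def features_at(positions, chrom="chrA", halfwidth=200):
    return FeatureSet(
        [GenomicInterval(chrom, max(p - halfwidth, 0), p + halfwidth) for p in positions]
    )


class TestOEBoundaryEnrichment:
    def test_features_at_boundaries_maximally_enriched(self):
        pos = [500_000, 1_500_000, 2_500_000, 3_500_000]
        bs = make_set(pos, size=8_000_000)
        res = oe_boundary_enrichment(features_at(pos), bs, n_perm=99, seed=0)
        assert res.oe_ratio > 1
        assert res.p_enrichment == pytest.approx(1 / 100)

    def test_observed_equals_bruteforce_overlap(self, rng):
        bpos = np.sort(rng.choice(700, 12, replace=False)) * 10_000
        fpos = rng.integers(0, 7_000_000, size=30)
        bs = make_set(bpos, size=8_000_000)
        res = oe_boundary_enrichment(features_at(fpos), bs, tol=10_000, n_perm=99, seed=1)
        brute = sum(1 for f in fpos if np.abs(bpos - f).min() <= 10_000)
        assert res.observed == brute

    def test_uniform_features_within_null_band(self):
        """Random features are not called enriched or depleted (most seeds)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bpos = np.sort(rng.choice(700, 15, replace=False)) * 10_000
            fpos = rng.integers(0, 7_000_000, size=25)
            res = oe_boundary_enrichment(
                features_at(fpos), make_set(bpos, size=8_000_000), n_perm=99, seed=seed + 7
            )
            hits += res.p <= 0.05
        assert hits <= 4

    def test_empty_inputs_rejected(self):
        bs = make_set([100_000])
        with pytest.raises(ValueError):
            oe_boundary_enrichment(FeatureSet([]), bs)
        with pytest.raises(ValueError):
            oe_boundary_enrichment(features_at([100]), bs, n_perm=10)

    def test_pvalues_never_zero(self, rng):
        bpos = np.sort(rng.choice(500, 10, replace=False)) * 10_000
        res = oe_boundary_enrichment(
            features_at(bpos * 1), make_set(bpos, size=8_000_000), n_perm=99, seed=3
        )
        assert 0 < res.p <= 1 and 0 < res.p_enrichment <= 1


GENES = pd.DataFrame(
    dict(
        gene_id=[f"g{i}" for i in range(40)],
        chrom=["chrA"] * 40,
        tss=np.arange(40) * 100_000 + 50_000,
    )
)


class TestGenesetEnrichment:
    def test_query_near_target_set_ranks_first(self, rng):
        target = {"TARGET": [f"g{i}" for i in range(10)], "OTHER": [f"g{i}" for i in range(20, 30)]}
        query = features_at(GENES["tss"].iloc[:8].to_numpy())  # adjacent to TARGET genes
        pool = features_at(rng.integers(0, 4_000_000, size=60))
        out = geneset_enrichment_vs_constant(query, pool, GENES, target, n_subsets=100, seed=0)
        best = out.sort_values("ratio", ascending=False).iloc[0]
        assert best["gene_set"] == "TARGET"
        assert best["p"] <= 0.05

    def test_query_from_pool_ratio_near_one(self):
        genes = pd.DataFrame(
            dict(
                gene_id=[f"g{i}" for i in range(200)],
                chrom=["chrA"] * 200,
                tss=np.arange(200) * 20_000 + 10_000,
            )
        )
        sets = {"S": [f"g{i}" for i in range(0, 200, 2)]}
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pool_pos = rng.integers(0, 4_000_000, size=100)
            pool = features_at(pool_pos)
            query = features_at(rng.choice(pool_pos, size=30, replace=False))
            out = geneset_enrichment_vs_constant(query, pool, genes, sets, n_subsets=100, seed=seed)
            ratios.append(out["ratio"].iloc[0])
        assert abs(np.mean(ratios) - 1.0) < 0.25

    def test_subset_count_bookkeeping(self, rng):
        query = features_at(rng.integers(0, 4_000_000, size=10))
        pool = features_at(rng.integers(0, 4_000_000, size=30))
        out = geneset_enrichment_vs_constant(
            query, pool, GENES, {"S": ["g1", "g2"]}, n_subsets=100, seed=1
        )
        assert (out["n_subsets"] == 100).all()

    def test_unmappable_set_skipped_with_warning(self, rng):
        query = features_at(rng.integers(0, 4_000_000, size=5))
        pool = features_at(rng.integers(0, 4_000_000, size=20))
        with pytest.warns(UserWarning):
            out = geneset_enrichment_vs_constant(
                query, pool, GENES, {"GHOST": ["nope"]}, n_subsets=100, seed=1
            )
        assert len(out) == 0

    def test_small_pool_rejected(self, rng):
        query = features_at(rng.integers(0, 4_000_000, size=10))
        pool = features_at(rng.integers(0, 4_000_000, size=5))
        with pytest.raises(ValueError):
            geneset_enrichment_vs_constant(query, pool, GENES, {"S": ["g1"]})


def expression_frame(tss, log2fc, chrom="chrA"):
    return pd.DataFrame(
        dict(
            gene_id=[f"g{i}" for i in range(len(tss))],
            chrom=[chrom] * len(tss),
            tss=tss,
            log2fc=log2fc,
        )
    )


class TestBoundaryExpressionAssociation:
    def test_class_means_match_bruteforce(self, rng):
        lost = np.sort(rng.choice(700, 10, replace=False)) * 10_000
        gained = np.sort(rng.choice(700, 8, replace=False)) * 10_000
        table = adjacency_table(lost, gained)
        tss = rng.integers(0, 8_000_000, size=200)
        lfc = rng.normal(0, 1, size=200)
        expr = expression_frame(tss, lfc)
        out = boundary_expression_association(table, expr, tol=10_000).set_index("class_")
        for cls, pos in (("lost", lost), ("gained", gained)):
            near = np.array([np.abs(pos - t).min() <= 10_000 for t in tss])
            if near.any():
                assert out.loc[cls, "mean_log2fc"] == pytest.approx(lfc[near].mean())
                assert out.loc[cls, "n_genes"] == near.sum()

    def test_zero_expression_null(self, rng):
        table = adjacency_table(np.array([100_000]), np.array([500_000]))
        tss = np.concatenate([[99_000, 501_000], rng.integers(0, 8_000_000, 100)])
        expr = expression_frame(tss, np.zeros(len(tss)))
        out = boundary_expression_association(table, expr).set_index("class_")
        assert out["mean_log2fc"].dropna().abs().max() == 0.0
        assert (out["p"].dropna() > 0.5).all()

    def test_empty_class_reported_without_p(self):
        table = adjacency_table(np.array([100_000]), np.array([5_000_000]))
        expr = expression_frame([100_001], [2.0])
        out = boundary_expression_association(table, expr).set_index("class_")
        assert out.loc["gained", "n_genes"] == 0
        assert np.isnan(out.loc["gained", "p"])


class TestDeltaDeltaCorrelation:
    def make_features(self, pos, logfc, chrom="chrA"):
        return pd.DataFrame(dict(chrom=[chrom] * len(pos), pos=pos, logfc=logfc))

    def test_identity_coupling_r_one(self):
        tss = np.arange(10) * 100_000 + 50_000
        lfc = np.linspace(-2, 2, 10)
        feats = self.make_features(tss, lfc)
        r, p, n = delta_delta_correlation(feats, expression_frame(tss, lfc))
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_matches_bruteforce_rank_correlation(self, rng):
        tss = np.arange(8) * 100_000 + 50_000
        flfc = rng.normal(0, 1, 8)
        glfc = rng.normal(0, 1, 8)
        feats = self.make_features(tss + 500, flfc)
        r, p, n = delta_delta_correlation(feats, expression_frame(tss, glfc), tol=3_000)
        expect = stats.spearmanr(flfc, glfc)
        assert n == 8
        assert r == pytest.approx(float(expect.statistic))
        assert p == pytest.approx(float(expect.pvalue))

    def test_nearest_feature_chosen_per_gene(self):
        feats = self.make_features([49_000, 52_000], [5.0, -5.0])
        expr = expression_frame([50_000, 150_000, 250_000], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            delta_delta_correlation(feats, expr, tol=3_000)

    def test_too_few_pairs_rejected(self):
        feats = self.make_features([50_000], [1.0])
        with pytest.raises(ValueError):
            delta_delta_correlation(feats, expression_frame([50_000], [1.0]))


class TestCorrelationRanking:
    def make_matrix(self, rng, n_genes=6, n_samples=6):
        data = rng.uniform(0, 10, size=(n_genes, n_samples))
        return pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])

    def test_identical_gene_tops_ranking(self, rng):
        m = self.make_matrix(rng)
        m.loc["twin"] = m.loc["g0"] * 2.0  # same ranks as the reference
        out = correlation_ranking(m, "g0")
        assert out.iloc[0]["gene"] == "twin"
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_exact_permutation_p_matches_enumeration(self, rng):
        """For n = 6 samples the p equals full enumeration over 720 orders."""
        x = rng.uniform(0, 1, 6)
        y = rng.uniform(0, 1, 6)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert _exact_spearman_p(x, y) == pytest.approx(count / 720)

    def test_zero_variance_gene_excluded(self, rng):
        m = self.make_matrix(rng)
        m.loc["flat"] = 3.0
        with pytest.warns(UserWarning):
            out = correlation_ranking(m, "g0")
        assert "flat" not in set(out["gene"])

    def test_zero_variance_reference_rejected(self, rng):
        m = self.make_matrix(rng)
        m.loc["flat"] = 3.0
        with pytest.raises(ValueError):
            correlation_ranking(m, "flat")

    def test_too_few_samples_rejected(self, rng):
        m = self.make_matrix(rng, n_samples=4)
        with pytest.raises(ValueError):
            correlation_ranking(m, "g0")

    def test_independent_gene_p_roughly_uniform(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            m = pd.DataFrame(rng.uniform(0, 1, size=(2, 9)), index=["ref", "x"])
            ps.append(correlation_ranking(m, "ref")["p"].iloc[0])
        ps = np.asarray(ps)
        assert np.mean(ps <= 0.1) < 0.25
        assert np.mean(ps <= 0.5) > 0.25
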