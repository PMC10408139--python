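"""Ranking, the weighted-KS enrichment score, permutation GSEA, discordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxsig.enrichment import (
    GeneSetCollection,
    RankedList,
    discordant_pathways,
    enrichment_score,
    gsea_preranked,
    nes_matrix,
    rank_genes,
    read_gmt,
    write_gmt,
)


def _deg(genes, lfc, p):
    return pd.DataFrame({"log2_fold_change": lfc, "p_value": p}, index=genes)


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return RankedList(genes=tuple(genes), scores=np.asarray(scores, dtype=float))


def _step_through_es(genes, scores, gene_set, weight):
    """Independent step-through oracle for the running sum."""
    hits = [g in gene_set for g in genes]
    weights = [abs(s) ** weight for s in scores]
    denom = sum(w for w, h in zip(weights, hits) if h)
    n_miss = len(genes) - sum(hits)
    running, total = [], 0.0
    for h, w in zip(hits, weights):
        total += w / denom if h else -1.0 / n_miss
        running.append(total)
    es = max(running, key=abs)
    return es, running


class TestRankGenes:
    def test_sign_and_evidence_ordering(self):
        deg = _deg(["a", "b"], [1.0, -1.0], [0.01, 0.01])
        ranked = rank_genes(deg)
        assert ranked.genes == ("a", "b")
        assert ranked.scores[0] > 0 > ranked.scores[1]

    def test_p_one_gives_zero_metric(self):
        ranked = rank_genes(_deg(["a"], [-3.0], [1.0]))
        assert ranked.scores[0] == 0.0

    def test_ties_broken_lexicographically_and_recorded(self):
        deg = _deg(["zz", "aa", "mm"], [1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        ranked = rank_genes(deg)
        assert ranked.genes == ("aa", "mm", "zz")
        assert ranked.ties == (("aa", "mm", "zz"),)

    def test_rejects_duplicates_and_bad_p(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_genes(_deg(["a", "a"], [1, 2], [0.1, 0.2]))
        with pytest.raises(ValueError, match="p-values"):
            rank_genes(_deg(["a"], [1.0], [0.0]))

    def test_log2fc_metric_option(self):
        deg = _deg(["a", "b"], [0.5, 2.0], [0.001, 0.5])
        assert rank_genes(deg, metric="log2fc").genes == ("b", "a")


class TestEnrichmentScore:
    def test_top_block_reaches_one(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        es, running = enrichment_score(ranked, {"g0", "g1"})
        assert es == pytest.approx(1.0)
        assert max(running) == pytest.approx(1.0)

    def test_weight_zero_is_classical_ks(self):
        ranked = _ranked([5, 4, 1, -3, -6])
        gene_set = {"g0", "g3"}
        es, _ = enrichment_score(ranked, gene_set, weight_exponent=0)
        # classical two-sample KS on ranks: sup |F_hit - F_miss|
        hits = np.array([g in gene_set for g in ranked.genes])
        f_hit = np.cumsum(hits) / hits.sum()
        f_miss = np.cumsum(~hits) / (~hits).sum()
        assert es == pytest.approx(np.max(np.abs(f_hit - f_miss)) *
                                   np.sign((f_hit - f_miss)[np.argmax(np.abs(f_hit - f_miss))]))
        assert es == pytest.approx(0.5)

    def test_matches_step_through_oracle(self):
        ranked = _ranked([5, 4, 1, -3, -6])
        for gene_set in [{"g0", "g3"}, {"g1"}, {"g2", "g4"}, {"g0", "g1", "g4"}]:
            for w in (0.0, 1.0, 2.0):
                es, running = enrichment_score(ranked, gene_set, weight_exponent=w)
                es_oracle, running_oracle = _step_through_es(
                    ranked.genes, ranked.scores, gene_set, w)
                assert es == pytest.approx(es_oracle, abs=1e-12)
                np.testing.assert_allclose(running, running_oracle, atol=1e-12)

    def test_no_hits_or_full_cover_rejected(self):
        ranked = _ranked([3, 2, 1])
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(ranked, {"zzz"})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, {"g0", "g1", "g2"})

    def test_negating_scores_reverses_and_negates(self, rng):
        scores = np.sort(rng.normal(size=40))[::-1]
        genes = [f"g{i}" for i in range(40)]
        ranked = _ranked(scores, genes)
        flipped = _ranked(-scores[::-1], genes[::-1])
        gene_set = set(rng.choice(genes, size=8, replace=False))
        es, _ = enrichment_score(ranked, gene_set)
        es_f, _ = enrichment_score(flipped, gene_set)
        assert es_f == pytest.approx(-es, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 15))
    def test_es_bounded_in_unit_interval(self, seed, set_size):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=50))[::-1]
        genes = [f"g{i}" for i in range(50)]
        members = set(rng.choice(genes, size=set_size, replace=False))
        es, _ = enrichment_score(_ranked(scores, genes), members)
        assert -1.0 <= es <= 1.0


def _planted_collection(ranked, extra_random=3, rng=None):
    sets = {"PLANTED": frozenset(ranked.genes[:20])}
    rng = rng or np.random.default_rng(0)
    for i in range(extra_random):
        sets[f"RND{i}"] = frozenset(rng.choice(ranked.genes, 20, replace=False))
    return GeneSetCollection(sets=sets)


@pytest.fixture(scope="module")
def null_ranking():
    rng = np.random.default_rng(99)
    scores = np.sort(rng.normal(size=1000))[::-1]
    return _ranked(scores, [f"g{i:04d}" for i in range(1000)])


class TestGseaPreranked:
    def test_planted_top_set_highly_significant(self, null_ranking):
        collection = _planted_collection(null_ranking)
        res = gsea_preranked(null_ranking, collection, seed=5, n_perm=1000)
        planted = res.loc["PLANTED"]
        assert planted.p <= 0.001
        assert planted.q < 0.25
        assert planted.es > 0 and planted.nes > 1

    def test_same_seed_identical_results(self, null_ranking):
        collection = _planted_collection(null_ranking)
        a = gsea_preranked(null_ranking, collection, seed=3, n_perm=100)
        b = gsea_preranked(null_ranking, collection, seed=3, n_perm=100)
        pd.testing.assert_frame_equal(a, b)

    def test_es_independent_of_permutation_count(self, null_ranking):
        collection = _planted_collection(null_ranking)
        a = gsea_preranked(null_ranking, collection, seed=3, n_perm=10)
        b = gsea_preranked(null_ranking, collection, seed=4, n_perm=500)
        np.testing.assert_array_equal(a.es.to_numpy(), b.es.to_numpy())

    def test_nes_sign_matches_es_sign(self, null_ranking):
        collection = _planted_collection(null_ranking, extra_random=8)
        res = gsea_preranked(null_ranking, collection, seed=7, n_perm=200)
        ok = res.dropna(subset=["nes"])
        assert (np.sign(ok.nes) == np.sign(ok.es)).all()
        assert ((res.q >= 0) & (res.q <= 1)).all()

    def test_size_filter_and_empty_error(self, null_ranking):
        tiny = GeneSetCollection(sets={"TINY": frozenset(null_ranking.genes[:2])})
        with pytest.raises(ValueError, match="size filter"):
            gsea_preranked(null_ranking, tiny, seed=0)

    def test_null_sets_type_i_calibrated(self, null_ranking):
        """Random sets on a null ranking: P(p < alpha) ~ alpha."""
        rng = np.random.default_rng(11)
        n_sets = 150
        sets = {
            f"S{i:03d}": frozenset(rng.choice(null_ranking.genes, 15, replace=False))
            for i in range(n_sets)
        }
        res = gsea_preranked(null_ranking, GeneSetCollection(sets=sets),
                             seed=13, n_perm=100)
        for alpha in (0.05, 0.25):
            frac = (res.p < alpha).mean()
            assert abs(frac - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_sets)


class TestNesMatrixAndDiscordance:
    @staticmethod
    def _result(rows):
        df = pd.DataFrame(rows, columns=["nes", "q"])
        df.index = [f"P{i}" for i in range(len(rows))]
        return df

    def test_retention_rules(self):
        a = self._result([(2.0, 0.01), (1.5, 0.5), (-1.8, 0.1)])
        b = self._result([(1.0, 0.9), (-2.0, 0.05), (1.7, 0.2)])
        nes = nes_matrix({"A": a, "B": b})
        assert np.isnan(nes.loc["P0", "B"]) and nes.loc["P0", "A"] == 2.0
        assert nes.loc["P1", "B"] == -2.0 and np.isnan(nes.loc["P1", "A"])

    def test_all_insignificant_warns_empty(self):
        a = self._result([(2.0, 0.9)])
        b = self._result([(1.0, 0.9)])
        with pytest.warns(UserWarning, match="no pathway"):
            nes = nes_matrix({"A": a, "B": b})
        assert nes.empty

    def test_contrast_collision_rejected(self):
        a = self._result([(2.0, 0.01)])
        with pytest.raises(ValueError, match="collision"):
            nes_matrix([("A", a), ("A", a)])

    def test_discordance_rules(self):
        nes = pd.DataFrame(
            {"A": [2.1, 2.1, 1.5, -1.2], "B": [-1.8, np.nan, 1.1, 2.5]},
            index=["opp", "onesided", "same", "opp2"],
        )
        out = discordant_pathways(nes, "A", "B")
        assert list(out.index) == ["opp", "opp2"]  # sorted by |NES gap|
        assert out.loc["opp", "gap"] == pytest.approx(3.9)
        with pytest.raises(ValueError, match="unknown contrast"):
            discordant_pathways(nes, "A", "Z")


class TestGmtIO:
    def test_roundtrip_and_dedup(self, tmp_path):
        f = tmp_path / "sets.gmt"
        f.write_text("SET1\tdesc\tg1\tg2\tg2\nSET2\t\tg3\n")
        coll = read_gmt(f)
        assert coll.sets["SET1"] == {"g1", "g2"}
        write_gmt(coll, tmp_path / "out.gmt")
        again = read_gmt(tmp_path / "out.gmt")
        assert again.sets == coll.sets

    def test_malformed_rejected(self, tmp_path):
        f = tmp_path / "bad.gmt"
        f.write_text("ONLYNAME\tdesc\n")
        with pytest.raises(ValueError, match=">= 3"):
            read_gmt(f)
        f.write_text("A\td\tg1\nA\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(f)
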