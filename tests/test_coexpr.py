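import numpy as np
import pandas as pd
import pytest

from seedhet import coexpr, qc
from seedhet.datatypes import GeneModule, SignatureScores, ValidationError
from seedhet.simulate import SimConfig, simulate_experiment

from conftest import make_normalized

SINGLE_COND = dict(conditions=("3d",), condition_means=(0.0,), tail_fraction=0.0)


def _prepared(seed, **kwargs):
    m, t = simulate_experiment(SimConfig(**kwargs), seed)
    kept, _ = qc.filter_low_expressed(m)
    kept, _ = qc.filter_intergenic_correlated(kept)
    return m, t, qc.normalize_counts(kept)


class TestGeneCorrelation:
    def test_duplicated_gene_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.random(10)
        nm = make_normalized(np.column_stack([x, x, rng.random(10)]))
        corr = coexpr.gene_correlation(nm)
        assert corr.loc["g0", "g1"] == pytest.approx(1.0)

    def test_negated_gene_is_anti_correlated(self):
        rng = np.random.default_rng(1)
        x = rng.random(10)
        nm = make_normalized(np.column_stack([x, 5.0 - x]))
        assert coexpr.gene_correlation(nm).loc["g0", "g1"] == pytest.approx(-1.0)

    def test_zero_variance_gene_named_in_error(self):
        nm = make_normalized(np.column_stack([np.ones(5), np.arange(5.0)]))
        with pytest.raises(ValidationError, match="g0"):
            coexpr.gene_correlation(nm)

    def test_independent_genes_rarely_cross_threshold(self):
        m, t, nm = _prepared(2, lam=0.0, n_genes=200, module_size=10, **SINGLE_COND)
        corr = coexpr.gene_correlation(nm).to_numpy()
        iu = np.triu_indices_from(corr, k=1)
        assert (np.abs(corr[iu]) > 0.5).mean() < 0.01


class TestModules:
    def _block_corr(self, blocks, r, n_noise=0):
        genes = [f"g{i}" for i in range(sum(blocks) + n_noise)]
        c = np.eye(len(genes)) * 1.0
        start = 0
        for size in blocks:
            c[start : start + size, start : start + size] = r
            start += size
        np.fill_diagonal(c, 1.0)
        return pd.DataFrame(c, index=genes, columns=genes)

    def test_two_blocks_found(self):
        corr = self._block_corr([5, 5], 0.9, n_noise=3)
        mods = coexpr.correlation_graph_modules(corr, 0.5, min_size=3)
        assert [len(m.genes) for m in mods] == [5, 5]
        assert mods[0].label == "cluster 1"

    def test_threshold_is_strict(self):
        corr = self._block_corr([2], 0.5)
        assert coexpr.correlation_graph_modules(corr, 0.5, min_size=2) == []

    def test_small_components_dropped(self):
        corr = self._block_corr([5, 2], 0.9)
        mods = coexpr.correlation_graph_modules(corr, 0.5, min_size=3)
        assert [len(m.genes) for m in mods] == [5]

    def test_label_order_size_then_lexicographic(self):
        corr = self._block_corr([4, 4], 0.9)
        mods = coexpr.correlation_graph_modules(corr, 0.5, min_size=2)
        assert min(mods[0].genes) == "g0"

    def test_planted_module_recovery(self):
        def jaccard(a, b):
            a, b = set(a), set(b)
            return len(a & b) / len(a | b)

        for seed in range(3):
            m, t, nm = _prepared(seed, **SINGLE_COND)
            corr = coexpr.gene_correlation(nm, nm.gene_ids[nm.values.std(axis=0) > 0])
            mods = coexpr.correlation_graph_modules(corr, 0.5, 10)
            assert len(mods) >= 2
            j_up = max(jaccard(mods[0].genes, t.module_up), jaccard(mods[1].genes, t.module_up))
            j_down = max(jaccard(mods[0].genes, t.module_down), jaccard(mods[1].genes, t.module_down))
            assert j_up >= 0.9 and j_down >= 0.9


class TestScores:
    def test_single_gene_module_score_is_that_gene(self):
        nm = make_normalized([[1.0, 9.0], [2.0, 8.0], [3.0, 7.0]])
        s = coexpr.module_score(nm, GeneModule("m", frozenset(["g1"])))
        assert s.scores.tolist() == [9.0, 8.0, 7.0]

    def test_constant_matrix_gives_identical_scores(self):
        nm = make_normalized(np.full((4, 3), 2.5))
        s = coexpr.module_score(nm, GeneModule("m", frozenset(["g0", "g2"])))
        assert len(set(s.scores)) == 1

    def test_missing_gene_rejected(self):
        nm = make_normalized([[1.0], [2.0], [3.0]])
        with pytest.raises(ValidationError):
            coexpr.module_score(nm, GeneModule("m", frozenset(["nope"])))

    def test_module_score_tracks_latent_axis(self):
        m, t, nm = _prepared(4, **SINGLE_COND)
        up = GeneModule("up", frozenset(g for g in t.module_up if g in nm.gene_ids))
        s = coexpr.module_score(nm, up)
        r = np.corrcoef(s.scores, t.g.loc[s.seed_ids])[0, 1]
        assert abs(r) >= 0.9


class TestGerminationIndex:
    def test_sign_convention(self):
        nm = make_normalized([[3.0, 0.0], [0.0, 3.0]])
        up = GeneModule("up", frozenset(["g0"]))
        down = GeneModule("down", frozenset(["g1"]))
        idx = coexpr.germination_index(nm, up, down)
        assert idx.scores.iloc[0] > 0 > idx.scores.iloc[1]

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        nm = make_normalized(rng.random((6, 4)))
        a = GeneModule("a", frozenset(["g0", "g1"]))
        b = GeneModule("b", frozenset(["g2", "g3"]))
        fwd = coexpr.germination_index(nm, a, b).scores
        rev = coexpr.germination_index(nm, b, a).scores
        assert (fwd == -rev).all()

    def test_overlap_rejected(self):
        nm = make_normalized(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValidationError):
            coexpr.germination_index(
                nm, GeneModule("a", frozenset(["g0", "g1"])), GeneModule("b", frozenset(["g1"]))
            )


class TestSizeSignature:
    def test_sign_convention_large_seedlike_positive(self):
        nm = make_normalized([[4.0, 0.0], [0.0, 4.0]])
        sig = coexpr.size_signature(nm, up_in_small=["g1"], up_in_large=["g0"])
        assert sig.scores.iloc[0] > 0 > sig.scores.iloc[1]

    def test_balanced_expression_gives_zero(self):
        nm = make_normalized(np.full((3, 2), 1.7))
        sig = coexpr.size_signature(nm, up_in_small=["g0"], up_in_large=["g1"])
        assert (sig.scores == 0).all()

    def test_separates_size_classes(self):
        from seedhet import diffexpr

        m, t, nm = _prepared(6)
        large = list(nm.seed_ids[m.class_label.loc[nm.seed_ids] == "large"])
        small = list(nm.seed_ids[m.class_label.loc[nm.seed_ids] == "small"])
        de = diffexpr.de_genes(nm, large, small)
        sig = coexpr.size_signature(
            nm,
            up_in_small=set(de.index[de.significant & (de.log2fc < 0)]),
            up_in_large=set(de.index[de.significant & (de.log2fc > 0)]),
        )
        s_large = sig.scores.loc[large].to_numpy()
        s_small = sig.scores.loc[small].to_numpy()
        # AUC via rank-sum: fraction of (large, small) pairs with higher score
        import scipy.stats

        u = scipy.stats.mannwhitneyu(s_large, s_small).statistic
        auc = u / (len(s_large) * len(s_small))
        assert auc >= 0.8


class TestSignatureCorrelation:
    def _scores(self, arr):
        idx = pd.Index([f"s{i}" for i in range(len(arr))], name="seed_id")
        return SignatureScores(scores=pd.Series(np.asarray(arr, float), index=idx), definition="t")

    def test_self_correlation_is_one(self):
        s = self._scores(np.random.default_rng(0).random(10))
        r, p = coexpr.signature_correlation(s, s)
        assert r == pytest.approx(1.0)

    def test_independent_signatures_near_zero(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            r, _ = coexpr.signature_correlation(
                self._scores(rng.standard_normal(96)), self._scores(rng.standard_normal(96))
            )
            hits += abs(r) < 0.3
        assert hits >= 38  # null sd ~ 1/sqrt(95): |r| >= 0.3 is a ~3 sigma event

    def test_attenuated_coupling_recovered(self):
        # the size covariate touches expression only through the axis residual
        # eps (axis minus condition mean and tail shift): index = a*eps + noise
        # with noise independent of z, so the planted coupling attenuates as
        # corr(index, z) = corr(index, eps) * corr(eps, z)
        m, t, nm = _prepared(8)
        up = GeneModule("up", frozenset(g for g in t.module_up if g in nm.gene_ids))
        down = GeneModule("down", frozenset(g for g in t.module_down if g in nm.gene_ids))
        idx = coexpr.germination_index(nm, up, down)
        cond_mean = m.condition.map({"3d": 0.0, "7d24h": 0.5}).astype(float)
        tail = pd.Series(
            [t.tail_shift if s in t.tail_seeds else 0.0 for s in m.seed_ids], index=m.seed_ids
        )
        eps = (t.g - cond_mean - tail).loc[idx.seed_ids]
        z = t.z.loc[idx.seed_ids]
        target = np.corrcoef(idx.scores, eps)[0, 1] * np.corrcoef(eps, z)[0, 1]
        r_size = np.corrcoef(idx.scores, z)[0, 1]
        assert r_size == pytest.approx(target, abs=0.15)

    def test_mismatched_seeds_rejected(self):
        s1 = self._scores([1.0, 2.0, 3.0])
        s2 = self._scores([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValidationError):
            coexpr.signature_correlation(s1, s2)


class TestOrientation:
    def test_recovery_condition_identifies_up_module(self):
        for seed in range(3):
            m, t, nm = _prepared(seed)
            corr = coexpr.gene_correlation(nm, nm.gene_ids[nm.values.std(axis=0) > 0])
            mods = coexpr.correlation_graph_modules(corr, 0.5, 10)
            up, down = coexpr.orient_modules(
                nm, mods, m.condition.loc[nm.seed_ids], ["3d", "7d24h"]
            )
            # oriented up module overlaps the planted +lambda module
            assert len(up.genes & t.module_up) > len(up.genes & t.module_down)
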