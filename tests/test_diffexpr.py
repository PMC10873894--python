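import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from seedhet import diffexpr, qc
from seedhet.config import Config
from seedhet.datatypes import ValidationError

from conftest import make_count_matrix, make_normalized


def rank_sum_p_by_enumeration(a, b):
    """Independent oracle: enumerate all rank splits of the combined sample.

    Tie-free inputs only.  Two-sided p = probability, under random
    assignment of ranks to the first group, of a rank-sum at least as
    extreme (in either direction) as observed.
    """
    n, m = len(a), len(b)
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    u_lo = min(u_obs, n * m - u_obs)
    u_hi = n * m - u_lo
    hits = total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        hits += u <= u_lo or u >= u_hi
        total += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_worked_example_exact(self):
        _, p = diffexpr.wilcoxon_rank_sum([1.1, 2.0, 3.2], [4.5, 5.1, 6.3])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = diffexpr.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 9) for m in range(1, 9) if n + m <= 10])
    def test_exact_path_equals_enumeration(self, n, m):
        rng = np.random.default_rng(1000 * n + m)
        for _ in range(3):
            vals = rng.permutation(np.arange(1.0, n + m + 1.0))  # tie-free
            a, b = vals[:n], vals[n:]
            _, p = diffexpr.wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(rank_sum_p_by_enumeration(a, b), abs=1e-12)

    def test_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b = rng.standard_normal(12), rng.standard_normal(12)
            exact = scipy.stats.mannwhitneyu(a, b, method="exact").pvalue
            _, approx = diffexpr.wilcoxon_rank_sum(a, b)  # n+m=24 -> asymptotic path
            assert approx == pytest.approx(exact, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            diffexpr.wilcoxon_rank_sum([], [1.0])

    def test_statistic_is_rank_sum(self):
        w, _ = diffexpr.wilcoxon_rank_sum([10.0, 20.0], [1.0, 2.0])
        assert w == 3 + 4


class TestFoldChange:
    def _nm(self, mean_a, mean_b):
        # one gene; de-logged normalized means mean_a (2 seeds) and mean_b (2 seeds)
        vals = np.log1p([[mean_a], [mean_a], [mean_b], [mean_b]])
        return make_normalized(vals, method_tag="log1p_test")

    def test_hand_arithmetic(self):
        nm = self._nm(4.0, 2.0)
        lfc = diffexpr.log2_fold_change(nm, ["g0"], ["s0", "s1"], ["s2", "s3"], 0.1)
        assert lfc["g0"] == pytest.approx(math.log2(4.1 / 2.1), abs=1e-12)

    def test_identical_groups_zero(self):
        nm = self._nm(3.0, 3.0)
        assert diffexpr.log2_fold_change(nm, ["g0"], ["s0", "s1"], ["s2", "s3"])["g0"] == 0.0

    def test_swap_negates(self):
        nm = self._nm(4.0, 2.0)
        fwd = diffexpr.log2_fold_change(nm, ["g0"], ["s0", "s1"], ["s2", "s3"])
        rev = diffexpr.log2_fold_change(nm, ["g0"], ["s2", "s3"], ["s0", "s1"])
        assert fwd["g0"] == pytest.approx(-rev["g0"])


class TestBH:
    def step_up_oracle(self, p):
        """Independent BH: sort, multiply by n/rank, cumulative min from the top."""
        p = np.asarray(p, dtype=float)
        order = np.argsort(p, kind="mergesort")
        n = len(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj, 1.0)
        return out

    def test_worked_example(self):
        assert diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert diffexpr.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert diffexpr.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_independent_step_up_and_dominates_input(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            adj = diffexpr.bh_adjust(p)
            assert adj == pytest.approx(self.step_up_oracle(p), abs=1e-12)
            assert (adj >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            diffexpr.bh_adjust([0.5, 1.5])


class TestDEGenes:
    def test_fold_change_gate_blocks_small_effects(self):
        # strong p-value but |log2FC| below log2(1.2): not significant
        rng = np.random.default_rng(3)
        n = 200
        base = rng.poisson(1000, size=(2 * n, 1)) + np.r_[
            np.full(n, 150), np.zeros(n)
        ].astype(int)[:, None]
        pad = rng.poisson(1000, size=(2 * n, 1))  # second gene stabilizes totals
        m = make_count_matrix(np.hstack([base, pad]))
        nm = qc.normalize_counts(m)
        res = diffexpr.de_genes(nm, [f"s{i}" for i in range(n)], [f"s{i}" for i in range(n, 2 * n)])
        assert res.loc["g0", "p_adjusted"] < 0.05
        assert abs(res.loc["g0", "log2fc"]) < math.log2(1.2)
        assert not res.loc["g0", "significant"]

    def test_planted_twofold_shift_detected(self):
        rng = np.random.default_rng(4)
        n_genes, n_de, n = 2000, 100, 48
        rates = np.full(n_genes, 5.0)
        a = rng.poisson(np.where(np.arange(n_genes) < n_de, 2 * rates, rates), size=(n, n_genes))
        b = rng.poisson(rates, size=(n, n_genes))
        m = make_count_matrix(np.vstack([a, b]))
        nm = qc.normalize_counts(m)
        ga = [f"s{i}" for i in range(n)]
        gb = [f"s{i}" for i in range(n, 2 * n)]
        res = diffexpr.de_genes(nm, ga, gb)
        sensitivity = res["significant"].to_numpy()[:n_de].mean()
        false_calls = res["significant"].to_numpy()[n_de:].mean()
        assert sensitivity >= 0.8
        assert false_calls <= 0.05

    def test_low_power_flagged(self):
        nm = make_normalized(np.log1p(np.random.default_rng(0).random((4, 3))), "log1p_t")
        res = diffexpr.de_genes(nm, ["s0", "s1"], ["s2", "s3"])
        assert res.attrs["low_power"]


class TestMonotone:
    def test_counted_and_not_counted(self):
        # gene 0 means (1,2,3) monotone; gene 1 means (1,3,2) not
        vals = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]])
        nm = make_normalized(vals)
        frac = diffexpr.monotone_fraction(nm, ["g0", "g1"], [["s0"], ["s1"], ["s2"]])
        assert frac == 0.5

    def test_gradient_simulation(self):
        # linear size effect across three groups: DE genes stay monotone
        rng = np.random.default_rng(6)
        n, n_genes = 40, 50
        effects = rng.uniform(-1, 1, n_genes)
        groups = []
        rows = []
        for gi, level in enumerate([-1.0, 0.0, 1.0]):
            rates = 20 * np.exp(effects * level * 0.5)
            rows.append(rng.poisson(rates, size=(n, n_genes)))
            groups.append([f"s{gi * n + i}" for i in range(n)])
        m = make_count_matrix(np.vstack(rows))
        nm = qc.normalize_counts(m)
        # the gradient property concerns genes DE between the extremes
        de = diffexpr.de_genes(nm, groups[0], groups[2])
        de_gene_ids = list(de.index[de["significant"]])
        assert len(de_gene_ids) >= 10
        frac = diffexpr.monotone_fraction(nm, de_gene_ids, groups)
        assert frac >= 0.9

    def test_requires_three_groups(self):
        nm = make_normalized([[1.0], [2.0]])
        with pytest.raises(ValidationError):
            diffexpr.monotone_fraction(nm, ["g0"], [["s0"], ["s1"]])


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_bh_dominates_and_caps(p):
        """BH output is elementwise >= input and never exceeds 1."""
        adj = diffexpr.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.sets(st.text(alphabet="abcdef", min_size=1, max_size=3), max_size=10),
        st.sets(st.text(alphabet="abcdef", min_size=1, max_size=3), max_size=10),
    )
    def test_set_overlap_partitions(a, b):
        """The three overlap counts partition the union."""
        only_a, both, only_b = diffexpr.set_overlap(a, b)
        assert only_a + both + only_b == len(a | b)
        assert both == len(a & b)

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({"x", "y", "z"}, {"y", "z", "w"}, (1, 2, 1)),
        ({"a", "b"}, {"c"}, (2, 0, 1)),
        ({"a"}, {"a", "b", "c"}, (0, 1, 2)),
    ],
)
def test_set_overlap(a, b, expected):
    assert diffexpr.set_overlap(a, b) == expected
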