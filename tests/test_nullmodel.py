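import itertools

import numpy as np
import pandas as pd
import pytest

from degvote.affinity import consensus_scores
from degvote.nullmodel import (
    NullDistribution,
    annotate_empirical_p,
    empirical_pvalue,
    quantile_tail_test,
    read_null,
    simulate_null,
    write_null,
)
from conftest import random_affinity_matrix


def enumerate_null_exact(am):
    """Exhaustive enumeration over all per-column permutations of a tiny
    matrix: exact null pmf of the pooled consensus scores."""
    vals = np.nan_to_num(am.to_numpy(float), nan=0.0)
    n, c = vals.shape
    counts = {}
    total = 0
    for perms in itertools.product(itertools.permutations(range(n)),
                                   repeat=c):
        scores = np.zeros(n)
        for j, perm in enumerate(perms):
            scores += vals[list(perm), j]
        for s in scores:
            counts[int(round(s))] = counts.get(int(round(s)), 0) + 1
        total += n
    return {s: cnt / total for s, cnt in counts.items()}


class TestSimulateNull:
    def test_all_zero_matrix(self):
        am = pd.DataFrame(np.zeros((10, 3)),
                          index=pd.Index([f"G{i}" for i in range(10)],
                                         name="gene"))
        nd = simulate_null(am, n_perm=7, seed=0)
        assert nd.histogram == {0: 70}

    def test_two_by_one_exact_split(self):
        am = pd.DataFrame([[1.0], [-1.0]],
                          index=pd.Index(["A", "B"], name="gene"))
        nd = simulate_null(am, n_perm=4000, seed=1)
        # only two permutations exist; scores +1 and -1 each appear once
        # per permutation regardless, so the split is exactly half/half
        assert nd.histogram[1] == nd.histogram[-1] == 4000

    def test_matches_exhaustive_enumeration_3x2(self):
        am = pd.DataFrame([[1.0, -1.0], [0.0, 1.0], [-1.0, 0.0]],
                          index=pd.Index(list("ABC"), name="gene"))
        exact = enumerate_null_exact(am)
        n_perm = 10000
        nd = simulate_null(am, n_perm=n_perm, seed=2)
        pooled = nd.pooled_total
        for score, prob in exact.items():
            observed = nd.histogram.get(score, 0) / pooled
            # each permutation contributes 3 pooled (dependent) scores;
            # use n_perm as the effective sample size, conservatively
            se = np.sqrt(prob * (1 - prob) / n_perm)
            assert abs(observed - prob) <= 3 * se, score

    def test_column_marginals_preserved(self):
        rng = np.random.default_rng(3)
        am = random_affinity_matrix(rng, n_genes=30, n_comparisons=4)
        nd = simulate_null(am, n_perm=50, seed=4)
        # permutation cannot create scores beyond the column-sum bounds
        vals = np.nan_to_num(am.to_numpy(), nan=0.0)
        hi = int(np.sum(np.max(vals, axis=0)))
        lo = int(np.sum(np.min(vals, axis=0)))
        assert max(nd.histogram) <= hi
        assert min(nd.histogram) >= lo

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        am = random_affinity_matrix(rng)
        assert simulate_null(am, 20, seed=9).histogram == \
            simulate_null(am, 20, seed=9).histogram
        assert simulate_null(am, 20, seed=9).histogram != \
            simulate_null(am, 20, seed=10).histogram

    def test_symmetric_marginals_give_symmetric_null(self):
        rng = np.random.default_rng(6)
        vals = rng.choice([-1.0, 0.0, 1.0], size=(500, 6),
                          p=[0.2, 0.6, 0.2])
        am = pd.DataFrame(vals, index=pd.Index([f"G{i}" for i in range(500)],
                                               name="gene"))
        nd = simulate_null(am, 200, seed=7)
        mean = sum(s * c for s, c in nd.histogram.items()) / nd.pooled_total
        col_mean = np.nan_to_num(vals).mean(axis=0).sum()
        assert abs(mean - col_mean) < 0.05

    def test_bad_n_perm(self):
        am = pd.DataFrame([[1.0]], index=pd.Index(["A"], name="gene"))
        with pytest.raises(ValueError):
            simulate_null(am, 0, seed=0)

    def test_resample_scheme_runs(self):
        rng = np.random.default_rng(8)
        am = random_affinity_matrix(rng, n_genes=40, n_comparisons=3)
        nd = simulate_null(am, 30, seed=1, scheme="resample_columns")
        assert nd.pooled_total == 40 * 30


class TestEmpiricalPvalue:
    def test_pseudocount_floor(self):
        nd = NullDistribution({0: 100}, n_perm=10, n_genes=10,
                              n_comparisons=3, seed=0)
        assert empirical_pvalue(nd, 1, "ge") == pytest.approx(1 / 101)

    def test_total_mass_at_low_cutoff(self):
        nd = NullDistribution({0: 100}, n_perm=10, n_genes=10,
                              n_comparisons=3, seed=0)
        assert empirical_pvalue(nd, -3, "ge") == 1.0

    def test_count_ratio_without_pseudocount(self):
        nd = NullDistribution({0: 90, 2: 10}, n_perm=10, n_genes=10,
                              n_comparisons=3, seed=0)
        assert empirical_pvalue(nd, 2, "ge", pseudocount=0) == 0.10

    def test_monotone_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(11)
        am = random_affinity_matrix(rng, n_genes=100, n_comparisons=6)
        nd = simulate_null(am, 100, seed=12)
        ps = [empirical_pvalue(nd, c, "ge") for c in range(-7, 8)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(p > 0 for p in ps)


class TestAnnotateEmpiricalP:
    def test_zero_score_near_one_and_ties_equal(self):
        rng = np.random.default_rng(13)
        am = random_affinity_matrix(rng, n_genes=200, n_comparisons=5)
        ct = consensus_scores(am)
        nd = simulate_null(am, 100, seed=14)
        ct = annotate_empirical_p(ct, nd)
        zeros = ct[ct["consensus_score"] == 0]
        assert (zeros["empirical_p"] > 0.5).all()
        for _, grp in ct.groupby("consensus_score"):
            assert grp["empirical_p"].nunique() == 1

    def test_comparison_count_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        am = random_affinity_matrix(rng, n_genes=20, n_comparisons=4)
        ct = consensus_scores(am)
        nd = simulate_null(am.iloc[:, :3], 10, seed=0)
        with pytest.raises(ValueError, match="comparisons"):
            annotate_empirical_p(ct, nd)

    def test_planted_genes_get_smaller_p(self):
        from degvote.synth import GeneratorParams, generate_affinity
        p = GeneratorParams(n_genes=2000, n_planted=30, seed=21)
        am, truth = generate_affinity(p)
        ct = annotate_empirical_p(consensus_scores(am),
                                  simulate_null(am, 50, seed=22))
        planted = ct.loc[sorted(truth.planted_genes), "empirical_p"]
        background = ct.drop(index=sorted(truth.planted_genes))["empirical_p"]
        assert planted.median() < background.median()


class TestQuantileTailTest:
    def test_identical_multisets_not_significant(self):
        x = np.arange(1, 101)
        res = quantile_tail_test(x, -x, n_boot=2000, seed=1)
        assert res.stat == 0
        assert res.pvalue > 0.05

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(2)
        neg = rng.integers(1, 10, size=500)
        res = quantile_tail_test(neg + 10, -neg, n_boot=2000, seed=3)
        assert res.stat >= 10
        assert res.pvalue < 0.01

    def test_median_level_agrees_with_median_difference(self):
        rng = np.random.default_rng(4)
        pos = rng.integers(1, 20, 200)
        neg = -rng.integers(1, 10, 200)
        res = quantile_tail_test(pos, neg, q_level=0.5, n_boot=200, seed=5)
        assert np.sign(res.stat) == np.sign(
            np.median(pos) - np.median(np.abs(neg)))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            quantile_tail_test([], [1])
        with pytest.raises(ValueError):
            quantile_tail_test([1], [1], q_level=1.0)


def test_null_histogram_round_trip(tmp_path):
    rng = np.random.default_rng(30)
    am = random_affinity_matrix(rng, n_genes=25, n_comparisons=3)
    nd = simulate_null(am, 40, seed=31)
    write_null(nd, tmp_path / "null.tsv")
    back = read_null(tmp_path / "null.tsv")
    assert back.histogram == nd.histogram
    assert back.scheme == nd.scheme
    assert back.pooled_total == nd.pooled_total
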