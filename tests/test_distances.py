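import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mimseq import (
    bhattacharyya,
    component_contributions,
    enumerate_canonical_kmers,
    hellinger,
    symmetric_kl,
)
from mimseq.distances import (
    pairwise_bhattacharyya,
    pairwise_hellinger,
    pairwise_symmetric_kl,
    rows_bhattacharyya,
    rows_hellinger,
    rows_symmetric_kl,
)
from mimseq.kmers import AggregateDistribution, PerKmerStats

INDEX2 = enumerate_canonical_kmers(2)  # m = 10, convenient size


def agg(probs, index=INDEX2):
    probs = np.asarray(probs, dtype=float)
    return AggregateDistribution(index, probs / probs.sum(), 1.0)


def stats(means, variances, index=INDEX2):
    return PerKmerStats(index, np.asarray(means, float), np.asarray(variances, float))


# -- independent oracles: literal formula transcription, scalar loops --------

def oracle_symmetric_kl(p, q):
    total = 0.0
    for pj, qj in zip(p, q):
        total += pj * math.log2(pj / qj) + qj * math.log2(qj / pj)
    return total / 2.0


def oracle_hellinger(p, q):
    return math.sqrt(
        0.5 * sum((math.sqrt(pj) - math.sqrt(qj)) ** 2 for pj, qj in zip(p, q))
    )


def oracle_bhattacharyya(mp, vp, mq, vq):
    total = 0.0
    for a, b, c, d in zip(mp, vp, mq, vq):
        s = b + d
        total += (a - c) ** 2 / (4 * s) + 0.5 * math.log(s / (2 * math.sqrt(b * d)))
    return total


def random_distributions(rng, n_pairs=100, m=10):
    for _ in range(n_pairs):
        yield rng.dirichlet(np.full(m, 0.5)) + 1e-9, rng.dirichlet(np.full(m, 2.0)) + 1e-9


class TestOracleEquivalence:
    def test_kl_and_hellinger_match_literal_formulas(self, rng):
        for p, q in random_distributions(rng):
            p, q = p / p.sum(), q / q.sum()
            assert symmetric_kl(agg(p), agg(q)) == pytest.approx(
                oracle_symmetric_kl(p, q), abs=1e-12
            )
            assert hellinger(agg(p), agg(q)) == pytest.approx(
                oracle_hellinger(p, q), abs=1e-12
            )

    def test_bhattacharyya_matches_literal_formula(self, rng):
        for _ in range(100):
            mp, mq = rng.random(10) * 0.1, rng.random(10) * 0.1
            vp, vq = rng.random(10) * 0.01 + 1e-4, rng.random(10) * 0.01 + 1e-4
            assert bhattacharyya(stats(mp, vp), stats(mq, vq)) == pytest.approx(
                oracle_bhattacharyya(mp, vp, mq, vq), abs=1e-12
            )


class TestReferenceValues:
    def test_symmetric_kl_two_bin_example(self):
        index = enumerate_canonical_kmers(1)
        d = symmetric_kl(agg([0.5, 0.5], index), agg([0.25, 0.75], index))
        assert d == pytest.approx(0.19812, abs=1e-4)

    def test_hellinger_two_bin_example(self):
        index = enumerate_canonical_kmers(1)
        d = hellinger(agg([0.5, 0.5], index), agg([0.25, 0.75], index))
        assert d == pytest.approx(0.18459, abs=1e-4)

    def test_hellinger_disjoint_support_saturates(self):
        index = enumerate_canonical_kmers(1)
        p = AggregateDistribution(index, np.array([1.0, 0.0]), 0.0)
        q = AggregateDistribution(index, np.array([0.0, 1.0]), 0.0)
        assert hellinger(p, q) == pytest.approx(1.0)

    def test_bhattacharyya_mean_term(self):
        index = enumerate_canonical_kmers(1)
        # single informative component, equal variances: (mu diff)^2/(4*2v)
        d = bhattacharyya(
            stats([0.2, 0.0], [0.01, 0.01], index), stats([0.1, 0.0], [0.01, 0.01], index)
        )
        assert d == pytest.approx(0.125, abs=1e-12)

    def test_bhattacharyya_variance_term(self):
        index = enumerate_canonical_kmers(1)
        d = bhattacharyya(
            stats([0.2, 0.0], [0.01, 0.01], index), stats([0.2, 0.0], [0.04, 0.01], index)
        )
        assert d == pytest.approx(0.5 * math.log(0.05 / 0.04), abs=1e-12)


prob_vectors = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=10, max_size=10
).map(lambda xs: np.array(xs) / sum(xs))


class TestMetricProperties:
    @given(prob_vectors, prob_vectors)
    def test_symmetry_and_nonnegativity(self, p, q):
        dk = symmetric_kl(agg(p), agg(q))
        dh = hellinger(agg(p), agg(q))
        assert dk >= 0 and dh >= 0
        assert dk == pytest.approx(symmetric_kl(agg(q), agg(p)), rel=1e-9)
        assert dh == pytest.approx(hellinger(agg(q), agg(p)), rel=1e-9)
        assert 0 <= dh <= 1

    @given(prob_vectors)
    def test_zero_iff_identical(self, p):
        assert symmetric_kl(agg(p), agg(p)) == pytest.approx(0.0, abs=1e-12)
        assert hellinger(agg(p), agg(p)) == pytest.approx(0.0, abs=1e-12)
        s = stats(p, np.full(10, 0.01))
        assert bhattacharyya(s, s) == pytest.approx(0.0, abs=1e-12)

    @given(prob_vectors, prob_vectors, prob_vectors)
    def test_hellinger_triangle_inequality(self, p, q, r):
        assert hellinger(agg(p), agg(r)) <= (
            hellinger(agg(p), agg(q)) + hellinger(agg(q), agg(r)) + 1e-12
        )

    def test_kl_quadratic_in_small_perturbations(self, rng):
        """Chi-square limit: symmetric KL grows quadratically as q -> p."""
        p = rng.dirichlet(np.full(10, 5.0))
        delta = rng.normal(size=10)
        delta -= delta.mean()  # sum-zero direction
        delta /= np.abs(delta / p).max() * 2
        eps = np.logspace(-4, -2, 8)
        values = [symmetric_kl(agg(p), agg(p + e * delta)) for e in eps]
        slope = np.polyfit(np.log(eps), np.log(values), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)


class TestErrors:
    def test_mismatched_index_errors(self):
        other = enumerate_canonical_kmers(3)
        p = agg(np.full(10, 0.1))
        q = AggregateDistribution(other, np.full(32, 1 / 32), 1.0)
        for fn in (symmetric_kl, hellinger):
            with pytest.raises(ValueError):
                fn(p, q)

    def test_kl_rejects_zero_entries(self):
        index = enumerate_canonical_kmers(1)
        p = AggregateDistribution(index, np.array([1.0, 0.0]), 0.0)
        q = AggregateDistribution(index, np.array([0.5, 0.5]), 0.0)
        with pytest.raises(ValueError, match="positive"):
            symmetric_kl(p, q)

    def test_unknown_metric(self):
        p = agg(np.full(10, 0.1))
        with pytest.raises(ValueError):
            component_contributions(p, p, "jensen_shannon")


class TestContributions:
    def test_two_bin_kl_contributions(self):
        index = enumerate_canonical_kmers(1)
        c = component_contributions(
            agg([0.5, 0.5], index), agg([0.25, 0.75], index), "symmetric_kl"
        )
        # j-th summand of the halved symmetric KL:
        # j=0: (0.5*log2(2) + 0.25*log2(1/2))/2 = 0.125
        # j=1: (0.5*log2(2/3) + 0.75*log2(3/2))/2 = 0.07312
        assert c == pytest.approx([0.125, 0.07312], abs=1e-4)
        assert c.sum() == pytest.approx(0.19812, abs=1e-4)

    def test_contributions_sum_to_metric(self, rng):
        for p, q in random_distributions(rng, n_pairs=20):
            p, q = p / p.sum(), q / q.sum()
            ckl = component_contributions(agg(p), agg(q), "symmetric_kl")
            assert ckl.sum() == pytest.approx(symmetric_kl(agg(p), agg(q)), abs=1e-12)
            chl = component_contributions(agg(p), agg(q), "hellinger")
            assert chl.sum() == pytest.approx(hellinger(agg(p), agg(q)) ** 2, abs=1e-12)
            mp, vp = rng.random(10), rng.random(10) * 0.01 + 1e-4
            mq, vq = rng.random(10), rng.random(10) * 0.01 + 1e-4
            cbh = component_contributions(stats(mp, vp), stats(mq, vq), "bhattacharyya")
            assert cbh.sum() == pytest.approx(
                bhattacharyya(stats(mp, vp), stats(mq, vq)), abs=1e-12
            )

    def test_identical_inputs_give_zero_contributions(self):
        p = agg(np.full(10, 0.1))
        assert np.allclose(component_contributions(p, p, "symmetric_kl"), 0.0)


class TestVectorizedBatchForms:
    """The engine's batch routines must agree with the scalar definitions."""

    def test_pairwise_and_rows_match_scalar(self, rng):
        P = rng.dirichlet(np.full(10, 1.0), size=6) + 1e-9
        P /= P.sum(axis=1, keepdims=True)
        M = rng.random((6, 10)) * 0.1
        V = rng.random((6, 10)) * 0.01 + 1e-4
        aggs = [agg(p) for p in P]
        sts = [stats(m, v) for m, v in zip(M, V)]
        Dk, Dh = pairwise_symmetric_kl(P), pairwise_hellinger(P)
        Db = pairwise_bhattacharyya(M, V)
        for a in range(6):
            for b in range(6):
                assert Dk[a, b] == pytest.approx(
                    symmetric_kl(aggs[a], aggs[b]), abs=1e-10
                )
                assert Dh[a, b] == pytest.approx(hellinger(aggs[a], aggs[b]), abs=1e-10)
                assert Db[a, b] == pytest.approx(
                    bhattacharyya(sts[a], sts[b]), abs=1e-10
                )
        assert np.allclose(rows_symmetric_kl(P[0], P), Dk[0], atol=1e-12)
        assert np.allclose(rows_hellinger(P[0], P), Dh[0], atol=1e-12)
        assert np.allclose(rows_bhattacharyya(M[0], V[0], M, V), Db[0], atol=1e-10)
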