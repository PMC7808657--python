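"""Subsampling-correction coefficients and the bias-corrected ⟨S⟩, ⟨I⟩ estimators."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from immfp import (
    Repertoire,
    downsample,
    expected_autologous_I,
    expected_autologous_S,
    expected_heterologous_scores,
    expected_sharing_from_frequencies,
    g_coefficient,
    h_coefficient,
    naive_autologous_S,
)
from immfp.synthetic import SyntheticConfig, generate_repertoire

from conftest import binom_pmf, g_by_enumeration


class TestGCoefficient:
    @pytest.mark.parametrize(
        "N,M,n,expected",
        [(4, 2, 1, 0.5), (4, 2, 0, 1.0), (10, 10, 1, 0.0), (6, 0, 3, 1.0)],
    )
    def test_reference_values(self, N, M, n, expected):
        assert g_coefficient(N, M, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """g equals the enumerated miss probability over every M-subset, N <= 8."""
        for N in range(1, 9):
            for M in range(N + 1):
                for n in range(N + 1):
                    assert g_coefficient(N, M, n) == pytest.approx(
                        g_by_enumeration(N, M, n), abs=1e-12
                    ), (N, M, n)

    def test_exact_rational_path_agrees(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(2, 101))
            M = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            assert g_coefficient(N, M, n) == pytest.approx(
                g_coefficient(N, M, n, exact=True), rel=1e-10
            )

    def test_stable_at_sequencing_scale(self):
        # for n = 1, g = (N-M)/N exactly
        N, M = 10_000_000, 10_000
        assert g_coefficient(N, M, 1) == pytest.approx((N - M) / N, rel=1e-9)
        assert 0.0 < g_coefficient(N, M, 5000) < 1.0

    def test_non_increasing_in_n(self):
        vals = [g_coefficient(100, 30, n) for n in range(101)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            g_coefficient(4, 5, 1)
        with pytest.raises(ValueError):
            g_coefficient(4, 2, 5)


class TestHCoefficient:
    @pytest.mark.parametrize(
        "N,M1,M2,n,expected",
        [
            (4, 2, 2, 4, 1.0),  # a clone holding every read is in both halves
            (4, 2, 2, 1, 0.0),  # a singleton falls in exactly one half
            (12, 0, 5, 3, 0.0),  # empty sample shares nothing
        ],
    )
    def test_reference_values(self, N, M1, M2, n, expected):
        assert h_coefficient(N, M1, M2, n) == pytest.approx(expected, abs=1e-12)

    def test_depth_requirement(self):
        with pytest.raises(ValueError, match="M1 \\+ M2"):
            h_coefficient(10, 6, 6, 2)

    def test_moment_identity_small_N(self):
        """Binomial expectation of h(n) reproduces the exact sharing probability."""
        for N in (5, 9, 12):
            for M1 in range(N + 1):
                for M2 in range(N - M1 + 1):
                    for f in (0.05, 0.3, 0.77):
                        lhs = sum(
                            binom_pmf(N, n, f) * h_coefficient(N, M1, M2, n)
                            for n in range(N + 1)
                        )
                        rhs = (1 - (1 - f) ** M1) * (1 - (1 - f) ** M2)
                        assert lhs == pytest.approx(rhs, abs=1e-12), (N, M1, M2, f)

    def test_polynomial_identity(self):
        """Σ_n C(N,n) x^n g_M(n) = (1+x)^(N-M)."""
        for N in (4, 8, 12):
            for M in (0, N // 2, N):
                for x in (0.3, 1.0, 2.7):
                    lhs = sum(
                        comb(N, n) * x**n * g_coefficient(N, M, n) for n in range(N + 1)
                    )
                    assert lhs == pytest.approx((1 + x) ** (N - M), rel=1e-12)


@pytest.fixture(scope="module")
def small_observed():
    rng = np.random.default_rng(21)
    truth = generate_repertoire(SyntheticConfig(n_clones=2000, seed=21), rng)
    deep = downsample(truth, 50_000, rng)
    return truth, deep


class TestExpectedScores:
    def test_monoclonal_always_shared(self):
        rep = Repertoire(pd.DataFrame({"cdr3_nt": ["AAGG"], "count": [10]}))
        assert expected_autologous_S(rep, 5, 5) == pytest.approx(1.0)

    def test_all_singletons_split_exactly(self):
        """With M1 + M2 = N, disjoint subsamples can never share a singleton."""
        tbl = pd.DataFrame({"cdr3_nt": [f"AAGG{'ACGT'[i%4]}{'ACGT'[i//4]}" for i in range(8)], "count": [1] * 8})
        rep = Repertoire(tbl)
        assert expected_autologous_S(rep, 4, 4) == pytest.approx(0.0, abs=1e-12)

    def test_corrected_below_naive_with_singletons(self, small_observed):
        _, deep = small_observed
        assert (deep.counts == 1).any()
        assert expected_autologous_S(deep, 1000, 1000) < naive_autologous_S(deep, 1000, 1000)

    def test_monotone_in_sample_sizes(self, small_observed):
        _, deep = small_observed
        vals = [expected_autologous_S(deep, M, 1000) for M in (100, 1000, 5000)]
        assert vals[0] <= vals[1] <= vals[2]
        vals2 = [expected_autologous_S(deep, 1000, M) for M in (100, 1000, 5000)]
        assert vals2[0] <= vals2[1] <= vals2[2]

    def test_shallow_data_falls_back_to_naive(self, small_observed):
        _, deep = small_observed
        N = deep.total_reads
        with pytest.warns(RuntimeWarning, match="naive"):
            val = expected_autologous_S(deep, N, N)
        assert val == pytest.approx(naive_autologous_S(deep, N, N))

    def test_matches_resampling_oracle(self, small_observed):
        """Corrected ⟨S⟩/⟨I⟩ from one deep dataset match the Monte-Carlo mean
        of the scores over paired samples drawn from the true frequencies."""
        truth, deep = small_observed
        f = truth.frequencies
        w = -np.log(truth.pgen) - 12.0
        M, reps = 1000, 400
        rng = np.random.default_rng(22)
        c1 = rng.multinomial(M, f, size=reps)
        c2 = rng.multinomial(M, f, size=reps)
        shared = (c1 > 0) & (c2 > 0)
        S_mc = shared.sum(axis=1)
        I_mc = (shared * w).sum(axis=1)
        est_S = expected_autologous_S(deep, M, M)
        est_I = expected_autologous_I(deep, M, M, gamma=12.0)
        assert abs(est_S - S_mc.mean()) < 3 * S_mc.std() / np.sqrt(reps) + 0.05 * S_mc.mean()
        assert abs(est_I - I_mc.mean()) < 3 * I_mc.std() / np.sqrt(reps) + 0.05 * abs(I_mc.mean())


class TestHeterologousExpectation:
    def test_disjoint_datasets(self):
        a = Repertoire(pd.DataFrame({"cdr3_nt": ["AAGG"], "count": [5]}))
        b = Repertoire(pd.DataFrame({"cdr3_nt": ["CCTT"], "count": [5]}))
        assert expected_heterologous_scores(a, b, 2, 2) == (0.0, 0.0)

    def test_shared_monoclonal_certain(self):
        a = Repertoire(pd.DataFrame({"cdr3_nt": ["AAGG"], "count": [5], "pgen": [1e-4]}))
        b = Repertoire(pd.DataFrame({"cdr3_nt": ["AAGG"], "count": [9], "pgen": [1e-4]}))
        S, I = expected_heterologous_scores(a, b, 5, 9, gamma=12.0)
        assert S == pytest.approx(1.0)
        assert I == pytest.approx(-np.log(1e-4) - 12.0)

    def test_matches_resampling_oracle(self):
        """⟨S⟩ for subsamples of two different datasets matches resampling."""
        rng = np.random.default_rng(30)
        t1 = generate_repertoire(SyntheticConfig(n_clones=2000, seed=31), rng)
        t2 = generate_repertoire(SyntheticConfig(n_clones=2000, seed=32), rng)
        d1 = downsample(t1, 50_000, rng)
        d2 = downsample(t2, 50_000, rng)
        M, reps = 1000, 400
        # oracle: resample subsamples of the DATASETS (the estimator predicts
        # sharing between subsamples of the observed reads)
        f1 = d1.frequencies
        f2 = d2.frequencies
        k1 = d1.keys
        k2 = d2.keys
        common = k1.intersection(k2)
        i1 = k1.get_indexer(common)
        i2 = k2.get_indexer(common)
        S_mc = np.empty(reps)
        # hypergeometric subsampling of reads without replacement
        for r in range(reps):
            c1 = rng.multivariate_hypergeometric(d1.counts, M)
            c2 = rng.multivariate_hypergeometric(d2.counts, M)
            S_mc[r] = np.sum((c1[i1] > 0) & (c2[i2] > 0))
        est_S, _ = expected_heterologous_scores(d1, d2, M, M, gamma=12.0)
        assert abs(est_S - S_mc.mean()) < 3 * S_mc.std() / np.sqrt(reps) + 0.05 * max(S_mc.mean(), 1)
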