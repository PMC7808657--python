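"""Bias-corrected expected S and I for hypothetical sample sizes.

A deep dataset of N reads lets us predict the sharing statistics of two
hypothetical samples of M1 and M2 cells drawn from the same blood. The naive
plug-in — treating the empirical read fractions n(s)/N as the true clone
frequencies — systematically overestimates sharing, because rare reads
(singletons in particular) overstate their clones' true frequencies.

The correction replaces the plug-in term for each clonotype by

    h(n) = 1 − g_{M1}(n) − g_{M2}(n) + g_{M1+M2}(n),
    g_M(n) = C(N−M, n) / C(N, n),

which is the unique polynomial-in-n weight whose binomial expectation equals
the exact sharing probability (1−(1−f)^{M1})(1−(1−f)^{M2}) for every true
frequency f. g_M(n) is also the probability that a uniformly chosen M-subset
of the N reads avoids all n reads of a clonotype, which is why the corrected
estimator is exactly unbiased under binomial read sampling.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from math import comb

import numpy as np

from .repertoire import Repertoire
from .scores import DEFAULT_GAMMA, shared_sequences

__all__ = [
    "g_coefficient",
    "h_coefficient",
    "expected_autologous_S",
    "expected_autologous_I",
    "expected_heterologous_scores",
    "naive_autologous_S",
    "naive_autologous_I",
    "expected_sharing_from_frequencies",
]


def _check_g_args(N: int, M: int, n: int) -> None:
    if not (0 <= M <= N):
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")


def g_coefficient(N: int, M: int, n: int, exact: bool = False) -> float:
    """Probability that an M-subset of N reads misses all n tagged reads.

    Equals C(N−M, n)/C(N, n); computed in log-gamma space so it is stable
    for N up to 10^7 and beyond. With ``exact=True`` the value is computed
    in exact rational arithmetic (intended for N ≤ ~100, as a cross-check).
    """
    _check_g_args(N, M, n)
    if n == 0:
        return 1.0
    if n > N - M:
        return 0.0
    if exact:
        return float(Fraction(comb(N - M, n), comb(N, n)))
    return float(_g_log(N, M, np.array([n], dtype=np.int64))[0])


def _g_log(N: int, M: int, n: np.ndarray) -> np.ndarray:
    """Vectorized g_M(n) over an integer array n (log-gamma space)."""
    from scipy.special import gammaln

    n = np.asarray(n, dtype=np.int64)
    out = np.zeros(n.shape, dtype=float)
    inside = n <= N - M
    out[~inside] = 0.0
    nn = n[inside]
    if nn.size == 0:
        return out
    # C(N-M, n)/C(N, n) = prod_{k<n} (N-M-k)/(N-k)
    if nn.max() <= 1 << 20:
        # cumulative log-product: avoids the catastrophic cancellation of
        # gammaln differences when N is large and n << N
        k = np.arange(nn.max(), dtype=float)
        steps = np.log((N - M - k) / (N - k))
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        log_g = cum[nn]
    else:
        log_g = (
            gammaln(N - M + 1)
            - gammaln(N - M - nn + 1)
            + gammaln(N - nn + 1)
            - gammaln(N + 1)
        )
    out[inside] = np.exp(log_g)
    return out


def h_coefficient(N: int, M1: int, M2: int, n: int) -> float:
    """Corrected sharing weight h(n) = 1 − g_{M1}(n) − g_{M2}(n) + g_{M1+M2}(n)."""
    if M1 + M2 > N:
        raise ValueError(
            f"h(n) requires M1 + M2 <= N (got {M1}+{M2} > {N}); "
            "the correction presumes a dataset deeper than the hypothetical samples"
        )
    _check_g_args(N, M1, n)
    _check_g_args(N, M2, n)
    return float(_h_array(N, M1, M2, np.array([n], dtype=np.int64))[0])


def _h_array(N: int, M1: int, M2: int, n: np.ndarray) -> np.ndarray:
    return 1.0 - _g_log(N, M1, n) - _g_log(N, M2, n) + _g_log(N, M1 + M2, n)


def _counts_or_raise(rep: Repertoire) -> tuple[np.ndarray, int]:
    counts = rep.counts
    N = int(counts.sum())
    return counts, N


def _h_weights(rep: Repertoire, M1: int, M2: int) -> np.ndarray:
    """Per-clonotype h(n(s)) weights, with a naive fallback for shallow data."""
    counts, N = _counts_or_raise(rep)
    if M1 < 0 or M2 < 0:
        raise ValueError("sample sizes must be non-negative")
    if M1 + M2 > N:
        warnings.warn(
            f"M1 + M2 = {M1 + M2} exceeds the dataset depth N = {N}; the "
            "subsampling correction is undefined and the naive plug-in "
            "estimate is returned instead",
            RuntimeWarning,
            stacklevel=3,
        )
        return _naive_weights(counts, N, M1, M2)
    uniq, inv = np.unique(counts, return_inverse=True)
    return _h_array(N, M1, M2, uniq)[inv]


def _naive_weights(counts: np.ndarray, N: int, M1: int, M2: int) -> np.ndarray:
    f = counts / N
    return -np.expm1(M1 * np.log1p(-f)) * -np.expm1(M2 * np.log1p(-f))


def expected_autologous_S(rep: Repertoire, M1: int, M2: int) -> float:
    """Bias-corrected ⟨S⟩ for two samples of M1 and M2 cells from one individual."""
    return float(_h_weights(rep, M1, M2).sum())


def expected_autologous_I(
    rep: Repertoire, M1: int, M2: int, gamma: float = DEFAULT_GAMMA
) -> float:
    """Bias-corrected ⟨I⟩ = Σ_s h(n(s)) [ln(1/pgen(s)) − γ].

    Clonotypes with missing or zero pgen are excluded, mirroring their
    exclusion from the I score itself.
    """
    w = _h_weights(rep, M1, M2)
    pgen = rep.pgen
    usable = np.isfinite(pgen) & (pgen > 0)
    if not usable.any():
        raise ValueError("no usable pgen values; annotate the repertoire first")
    return float((w[usable] * (-np.log(pgen[usable]) - gamma)).sum())


def naive_autologous_S(rep: Repertoire, M1: int, M2: int) -> float:
    """Naive plug-in ⟨S⟩ = Σ_s (1−(1−n/N)^{M1})(1−(1−n/N)^{M2}) (biased upward)."""
    counts, N = _counts_or_raise(rep)
    return float(_naive_weights(counts, N, M1, M2).sum())


def naive_autologous_I(
    rep: Repertoire, M1: int, M2: int, gamma: float = DEFAULT_GAMMA
) -> float:
    """Naive plug-in counterpart of :func:`expected_autologous_I`."""
    counts, N = _counts_or_raise(rep)
    w = _naive_weights(counts, N, M1, M2)
    pgen = rep.pgen
    usable = np.isfinite(pgen) & (pgen > 0)
    if not usable.any():
        raise ValueError("no usable pgen values; annotate the repertoire first")
    return float((w[usable] * (-np.log(pgen[usable]) - gamma)).sum())


def expected_heterologous_scores(
    rep1: Repertoire,
    rep2: Repertoire,
    M1: int,
    M2: int,
    gamma: float = DEFAULT_GAMMA,
) -> tuple[float, float]:
    """Expected (⟨S⟩, ⟨I⟩) for samples from two *different* deep datasets.

    Only clonotypes observed in both datasets can be shared by the
    subsamples, so the sums run over the shared keys, weighted by the
    probability of capturing the clonotype in each subsample:
    ⟨S⟩ = Σ_s [1 − g_{M1}(n(s))][1 − g_{M2}(n′(s))].
    """
    counts1, N1 = _counts_or_raise(rep1)
    counts2, N2 = _counts_or_raise(rep2)
    if M1 > N1 or M2 > N2:
        raise ValueError("subsample sizes cannot exceed the dataset depths")
    shared = shared_sequences(rep1, rep2)
    if len(shared) == 0:
        return 0.0, 0.0
    n1 = shared.counts1.astype(np.int64)
    n2 = shared.counts2.astype(np.int64)
    w = (1.0 - _g_log(N1, M1, n1)) * (1.0 - _g_log(N2, M2, n2))
    S = float(w.sum())
    usable = np.isfinite(shared.pgen) & (shared.pgen > 0)
    I = float((w[usable] * (-np.log(shared.pgen[usable]) - gamma)).sum())
    return S, I


def expected_sharing_from_frequencies(
    freqs: np.ndarray,
    M1: int,
    M2: int,
    weights: np.ndarray | None = None,
) -> float:
    """Exact ⟨S⟩ (or weighted ⟨I⟩) when the true clone frequencies are known.

    Computes Σ_s w_s (1−(1−f_s)^{M1})(1−(1−f_s)^{M2}); with ``weights`` set
    to ln(1/pgen) − γ this is the corresponding expected I. Used for
    synthetic ground-truth repertoires and for the turnover simulation, where
    frequencies are known rather than estimated from reads.
    """
    f = np.asarray(freqs, dtype=float)
    terms = -np.expm1(M1 * np.log1p(-f)) * -np.expm1(M2 * np.log1p(-f))
    if weights is not None:
        terms = terms * np.asarray(weights, dtype=float)
    return float(terms.sum())
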