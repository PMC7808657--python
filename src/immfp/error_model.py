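"""Analytic error-rate bounds, heterologous upper bounds, DET curves, AUROC.

The S statistic is a sum of independent Bernoulli variables (one per
potential sequence), i.e. Poisson-binomial; its variance and tails are
bounded by those of the Poisson distribution with the same mean, m_a in the
autologous scenario and m_h in the heterologous one. For a threshold r this
gives

    FNR ≤ Q(r+1, m_a),      FPR ≤ 1 − Q(r+1, m_h),

with Q the regularized upper incomplete gamma function (at integer r,
Q(r+1, m) is the Poisson CDF at r).

For the I statistic, conditionally on S the score is a sum of S independent
surprise terms ln(1/P_gen) − γ; by the central limit theorem that sum is
approximately normal with mean and variance proportional to S, giving a
compound Poisson-normal model. The surprise moments differ between the two
scenarios: sequences shared by chance between individuals are biased toward
high P_gen, so their surprise has lower mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf, gammaincc
from scipy.stats import poisson

from .estimators import expected_autologous_S
from .pgen import PgenProvider
from .repertoire import Repertoire
from .scores import DEFAULT_GAMMA, DecisionRule

__all__ = [
    "ScoreDistributionModel",
    "DecisionRule",
    "s_error_bounds",
    "i_error_rates",
    "heterologous_bound_S",
    "heterologous_bound_I",
    "det_and_auroc",
    "fit_model_from_data",
    "equal_error_rule",
]


@dataclass
class ScoreDistributionModel:
    """Poisson rates and surprise moments parameterizing the score distributions.

    ``m_a`` / ``m_h``: mean number of shared clonotypes in the autologous /
    heterologous scenario. ``surprise_mean`` / ``surprise_var``: moments of
    ln(1/P_gen) − γ for generic sequences (autologous sharing); the
    ``_shared`` pair is restricted to convergently shared sequences
    (heterologous sharing), which have systematically lower surprise.
    """

    m_a: float
    m_h: float
    surprise_mean: float
    surprise_var: float
    surprise_mean_shared: float
    surprise_var_shared: float
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self):
        if self.m_a < 0 or self.m_h < 0:
            raise ValueError("need m_a >= 0 and m_h >= 0")
        if self.surprise_var < 0 or self.surprise_var_shared < 0:
            raise ValueError("variances must be non-negative")


def s_error_bounds(r: float, model: ScoreDistributionModel) -> tuple[float, float]:
    """Poisson tail bounds on (FNR, FPR) for the S statistic at threshold r.

    FNR = Q(r+1, m_a) bounds P(S ≤ r | autologous); FPR = 1 − Q(r+1, m_h)
    bounds P(S > r | heterologous). The gamma-function form is kept exactly
    as stated, so non-integer r interpolates the Poisson partial sums.
    """
    if r < 0:
        raise ValueError("threshold r must be >= 0 for the S statistic")
    fnr = float(gammaincc(r + 1.0, model.m_a))
    fpr = float(1.0 - gammaincc(r + 1.0, model.m_h)) if model.m_h > 0 else 0.0
    return fnr, fpr


def _poisson_grid(m: float, truncation: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Support and pmf of Poisson(m) up to residual mass < truncation."""
    if m == 0:
        return np.array([], dtype=np.int64), np.array([]), 1.0
    hi = int(max(poisson.ppf(1.0 - truncation, m), m + 10.0 * np.sqrt(m))) + 1
    S = np.arange(1, hi + 1)
    return S, poisson.pmf(S, m), float(poisson.pmf(0, m))


def _normal_cdf_terms(r: float, S: np.ndarray, mu: float, var: float) -> np.ndarray:
    """P(N(S·mu, S·var) < r) for each S >= 1, handling the var = 0 limit."""
    if var == 0:
        return (r > S * mu).astype(float) + 0.5 * (r == S * mu)
    z = (r - S * mu) / np.sqrt(2.0 * S * var)
    return 0.5 * (1.0 + erf(z))


def i_error_rates(
    r: float, model: ScoreDistributionModel, truncation: float = 1e-12
) -> tuple[float, float]:
    """Compound Poisson-normal (FNR, FPR) for the I statistic at threshold r.

    FNR = P(I < r | autologous) uses rate m_a with the generic surprise
    moments; FPR = P(I > r | heterologous) uses rate m_h with the
    shared-sequence moments. The Poisson sums are truncated once the
    residual mass falls below ``truncation``. The S = 0 term is degenerate
    (I ≡ 0): it contributes the indicator of r ≷ 0.
    """
    S, pmf, p0 = _poisson_grid(model.m_a, truncation)
    fnr = p0 * (1.0 if r > 0 else 0.0)
    if len(S):
        fnr += float((pmf * _normal_cdf_terms(r, S, model.surprise_mean, model.surprise_var)).sum())

    S, pmf, p0 = _poisson_grid(model.m_h, truncation)
    fpr = p0 * (1.0 if r < 0 else 0.0)
    if len(S):
        fpr += float(
            (pmf * (1.0 - _normal_cdf_terms(r, S, model.surprise_mean_shared, model.surprise_var_shared))).sum()
        )
    return fnr, fpr


def _sample_p(provider: PgenProvider, q: float, n_draws: int, seed) -> np.ndarray:
    if not 0 < q <= 1:
        raise ValueError("selection factor q must lie in (0, 1]")
    if not hasattr(provider, "sample"):
        raise TypeError("provider must support .sample(n, seed) to estimate bounds")
    _, pgen = provider.sample(n_draws, seed)
    return pgen / q


def heterologous_bound_S(
    M1: int,
    M2: int,
    provider: PgenProvider,
    q: float = 1.0,
    n_draws: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Upper bound M1·M2·⟨p(s)⟩ on the mean heterologous S.

    p(s) = P_gen(s)/q is the probability that a given cell carries sequence
    s; ⟨p(s)⟩ is estimated as the mean of p over sequences drawn from the
    generative model (a generation-weighted average, i.e. the collision
    probability of the recombination process scaled by the selection factor).
    """
    if M1 == 0 or M2 == 0:
        return 0.0
    p = _sample_p(provider, q, n_draws, seed)
    return float(M1 * M2 * p.mean())


def heterologous_bound_I(
    M1: int,
    M2: int,
    provider: PgenProvider,
    q: float = 1.0,
    gamma: float = DEFAULT_GAMMA,
    n_draws: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Upper bound −M1·M2·⟨p(s)[γ + ln(q·p(s))]⟩ on the mean heterologous I.

    Since γ + ln(q·p) = −[ln(1/P_gen) − γ], this is the p-weighted mean
    surprise of convergently shared sequences, scaled by the number of
    cell-pair coincidences. It can be negative: convergent sharing is
    dominated by public (low-surprise) sequences.
    """
    if M1 == 0 or M2 == 0:
        return 0.0
    p = _sample_p(provider, q, n_draws, seed)
    return float(-M1 * M2 * (p * (gamma + np.log(q * p))).mean())


def det_and_auroc(
    model: ScoreDistributionModel,
    statistic: str = "I",
    r_grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, float]:
    """Sweep the threshold to build a DET curve and integrate the AUROC.

    Returns an array of (r, fnr, fpr) rows and the area under the ROC,
    computed by trapezoid integration of the true-negative rate (1 − FPR)
    against the FNR as r varies — equal to P(score_het < score_auto) under
    the model.
    """
    if statistic not in ("S", "I"):
        raise ValueError("statistic must be 'S' or 'I'")
    if r_grid is None:
        r_grid = default_threshold_grid(model, statistic)
    r_grid = np.asarray(list(r_grid), dtype=float)
    if r_grid.size == 0:
        raise ValueError("threshold grid is empty")
    rates = (
        np.array([s_error_bounds(r, model) for r in r_grid])
        if statistic == "S"
        else np.array([i_error_rates(r, model) for r in r_grid])
    )
    det = np.column_stack([r_grid, rates])
    fnr, fpr = rates[:, 0], rates[:, 1]
    order = np.argsort(fnr, kind="mergesort")
    x = np.concatenate([[0.0], fnr[order], [1.0]])
    y = np.concatenate([[0.0], 1.0 - fpr[order], [1.0]])
    auroc = float(np.trapezoid(y, x))
    return det, auroc


def default_threshold_grid(
    model: ScoreDistributionModel, statistic: str, n: int = 512
) -> np.ndarray:
    """A threshold grid wide enough to cover both score distributions."""
    if statistic == "S":
        hi = model.m_a + 10.0 * np.sqrt(model.m_a) + 10.0
        return np.linspace(0.0, hi, n)
    lo_core = model.m_h * model.surprise_mean_shared - 10.0 * np.sqrt(
        max(model.m_h, 1.0) * max(model.surprise_var_shared, 1e-12) + model.m_h * model.surprise_mean_shared**2
    )
    hi_core = model.m_a * model.surprise_mean + 10.0 * np.sqrt(
        model.m_a * max(model.surprise_var, 1e-12) + model.m_a * model.surprise_mean**2
    )
    lo = min(lo_core, -1.0)
    hi = max(hi_core, 1.0)
    return np.linspace(lo, hi, n)


def equal_error_rule(
    model: ScoreDistributionModel,
    statistic: str = "I",
    r_grid: Sequence[float] | None = None,
) -> DecisionRule:
    """Decision rule at the threshold minimizing max(FNR bound, FPR bound)."""
    det, _ = det_and_auroc(model, statistic, r_grid)
    worst = np.maximum(det[:, 1], det[:, 2])
    k = int(np.argmin(worst))
    return DecisionRule(
        statistic=statistic,
        threshold=float(det[k, 0]),
        fnr_bound=float(det[k, 1]),
        fpr_bound=float(det[k, 2]),
    )


def surprise_moments(
    provider: PgenProvider,
    gamma: float = DEFAULT_GAMMA,
    n_draws: int = 20000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mean and variance of ln(1/P_gen) − γ over generated sequences."""
    if not hasattr(provider, "sample"):
        raise TypeError("provider must support .sample(n, seed)")
    _, pgen = provider.sample(n_draws, seed)
    w = -np.log(pgen) - gamma
    return float(w.mean()), float(w.var())


def shared_surprise_moments(
    provider: PgenProvider,
    gamma: float = DEFAULT_GAMMA,
    n_draws: int = 20000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Surprise moments restricted to convergently shared sequences.

    Two synthetic cohorts of ``n_draws`` generated sequences stand in for two
    unrelated individuals; the moments are taken over the sequences generated
    in both cohorts (weighted by their occurrence, which favors high P_gen —
    exactly the bias that makes heterologous sharing "public"). Falls back to
    the generic moments, with a warning, if the cohorts share nothing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs1, pgen1 = provider.sample(n_draws, rng)
    seqs2, _ = provider.sample(n_draws, rng)
    in2 = set(seqs2)
    w = np.array(
        [-np.log(p) - gamma for s, p in zip(seqs1, pgen1) if s in in2], dtype=float
    )
    if len(w) < 2:
        warnings.warn(
            "synthetic cohorts share fewer than 2 sequences; falling back to generic "
            "surprise moments",
            RuntimeWarning,
        )
        return surprise_moments(provider, gamma, n_draws, rng)
    return float(w.mean()), float(w.var())


def fit_model_from_data(
    autologous_reps: Sequence[Repertoire],
    M1: int,
    M2: int,
    provider: PgenProvider,
    q: float = 1.0,
    gamma: float = DEFAULT_GAMMA,
    n_draws: int = 20000,
    seed: int | np.random.Generator = 0,
) -> ScoreDistributionModel:
    """Fit the score-distribution model from deep datasets plus a pgen model.

    ``m_a`` is the *smallest* corrected autologous ⟨S⟩ among the supplied
    repertoires (the worst-case individual governs the error bound);
    ``m_h`` comes from the semi-theoretical heterologous bound; the surprise
    moments are estimated by sampling the generative model.
    """
    if len(autologous_reps) == 0:
        raise ValueError("at least one repertoire is required to estimate m_a")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_a = min(expected_autologous_S(rep, M1, M2) for rep in autologous_reps)
    m_h = heterologous_bound_S(M1, M2, provider, q=q, n_draws=n_draws, seed=rng)
    mu, var = surprise_moments(provider, gamma, n_draws, rng)
    mu_sh, var_sh = shared_surprise_moments(provider, gamma, n_draws, rng)
    return ScoreDistributionModel(
        m_a=m_a,
        m_h=m_h,
        surprise_mean=mu,
        surprise_var=var,
        surprise_mean_shared=mu_sh,
        surprise_var_shared=var_sh,
        gamma=gamma,
    )
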