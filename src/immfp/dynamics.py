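"""Clone-frequency turnover dynamics and fingerprint decay.

Each clone's frequency f evolves independently under a fluctuating growth
rate; in log-frequency x = ln f the dynamics reduce to Brownian motion with
drift,

    dx = −dt/τ + θ^{−1/2} dW,

where τ is the clone turnover time and θ the growth-rate fluctuation
timescale (both in years). Euler–Maruyama integration of this log-space
equation is exact for Brownian motion, so the step size only controls how
often the extinction barrier is checked. Clones falling below an extinction
threshold (default 1e-11, about one cell in a human body) are removed.

With a steady source of new clones at small frequency, the stationary
clone-size density is a power law ρ(f) ∝ f^−α with α = 1 + 2θ/τ; the
empirical exponent α ≈ 2 corresponds to θ = τ/2, the package default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .repertoire import Repertoire
from .scores import DEFAULT_GAMMA

__all__ = [
    "DynamicsParams",
    "steady_state_exponent",
    "evolve_frequencies",
    "simulate_steady_state",
    "fit_power_law_exponent",
    "fingerprint_decay",
]

#: Default integration step: 2 days, in years.
DEFAULT_DT = 2.0 / 365.0


@dataclass
class DynamicsParams:
    """Parameters of the fluctuating-growth-rate clone dynamics.

    ``tau``: turnover time (years). ``theta``: fluctuation timescale (years);
    defaults to tau/2, which reproduces the empirically observed clone-size
    exponent α = 2. ``theta = inf`` disables the noise (pure exponential
    decay). ``dt``: integration step in years (default 2 days).
    """

    tau: float
    theta: Optional[float] = None
    dt: float = DEFAULT_DT
    extinction_threshold: float = 1e-11
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.theta is None:
            self.theta = self.tau / 2.0
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.extinction_threshold < 1:
            raise ValueError("extinction_threshold must lie in [0, 1)")


def steady_state_exponent(params: DynamicsParams) -> float:
    """Predicted stationary clone-size power-law exponent α = 1 + 2θ/τ."""
    return 1.0 + 2.0 * params.theta / params.tau


def _x_threshold(params: DynamicsParams) -> float:
    return -np.inf if params.extinction_threshold == 0 else np.log(params.extinction_threshold)


def _evolve_x(
    x: np.ndarray,
    params: DynamicsParams,
    t: float,
    rng: np.random.Generator,
    alive: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance log-frequencies by duration t; returns (x, alive mask)."""
    if t < 0:
        raise ValueError("duration must be non-negative")
    x = np.array(x, dtype=float)
    alive = np.ones(len(x), dtype=bool) if alive is None else alive.copy()
    x_ext = _x_threshold(params)
    sigma = 0.0 if np.isinf(params.theta) else 1.0 / np.sqrt(params.theta)
    n_full, rem = divmod(t, params.dt)
    steps = [params.dt] * int(n_full) + ([rem] if rem > 1e-12 else [])
    for dt in steps:
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        x[idx] += -dt / params.tau + sigma * np.sqrt(dt) * rng.standard_normal(len(idx))
        alive[idx] &= x[idx] >= x_ext
    return x, alive


def evolve_frequencies(
    freqs: Sequence[float],
    params: DynamicsParams,
    t: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evolve clone frequencies for duration t; extinct clones are removed.

    Frequencies are treated as independent per-clone processes and are *not*
    renormalized during evolution — renormalization would alter the
    stationary law. The same seed yields identical trajectories.
    """
    f = np.asarray(freqs, dtype=float)
    if len(f) and (np.any(f <= 0) or np.any(f > 1)):
        raise ValueError("frequencies must lie in (0, 1]")
    if t == 0:
        return f.copy()
    rng = np.random.default_rng(params.seed) if rng is None else rng
    x, alive = _evolve_x(np.log(f), params, t, rng)
    return np.exp(x[alive])


def simulate_steady_state(
    params: DynamicsParams,
    n_clones: int = 10000,
    t_total: float | None = None,
    f_source: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Run the dynamics with a small-f source of new clones to stationarity.

    New clones (thymic exports) are injected as a Poisson process at
    frequency ``f_source`` (default 10x the extinction threshold). The
    injection rate is set to ``n_clones / (τ ln(f_source/f_ext))``: with a
    net log-drift of −1/τ toward an absorbing barrier ln(f_ext), the mean
    clone lifetime is τ·ln(f_source/f_ext), so this rate holds the mean
    population at ``n_clones``. Default duration is 20 τ, enough for the
    intermediate-frequency range of the distribution to equilibrate.

    Returns the final frequencies of all surviving clones.
    """
    if params.extinction_threshold <= 0:
        raise ValueError("a positive extinction threshold is required for stationarity")
    f_source = 10.0 * params.extinction_threshold if f_source is None else f_source
    if f_source <= params.extinction_threshold:
        raise ValueError("f_source must exceed the extinction threshold")
    t_total = 20.0 * params.tau if t_total is None else t_total
    rng = np.random.default_rng(params.seed) if rng is None else rng

    x_src = np.log(f_source)
    x_ext = np.log(params.extinction_threshold)
    rate = n_clones / (params.tau * (x_src - x_ext))
    sigma = 1.0 / np.sqrt(params.theta)
    dt = params.dt
    n_steps = int(round(t_total / dt))

    x = np.full(rng.poisson(rate * params.tau * (x_src - x_ext)), x_src)  # warm head count
    for _ in range(n_steps):
        x += -dt / params.tau + sigma * np.sqrt(dt) * rng.standard_normal(len(x))
        x = x[x >= x_ext]
        n_new = rng.poisson(rate * dt)
        if n_new:
            x = np.concatenate([x, np.full(n_new, x_src)])
    return np.exp(x)


def fit_power_law_exponent(
    freqs: np.ndarray, f_lo: float, f_hi: float | None = None
) -> float:
    """Hill (maximum-likelihood) estimate of the power-law exponent α.

    For ρ(f) ∝ f^−α on [f_lo, ∞) the MLE is α̂ = 1 + n / Σ ln(f_i/f_lo)
    over the n frequencies above ``f_lo``. An optional upper cut ``f_hi``
    restricts the fit window; the estimator ignores the upper truncation,
    whose bias is negligible when the window spans several decades.
    """
    f = np.asarray(freqs, dtype=float)
    f = f[f >= f_lo]
    if f_hi is not None:
        f = f[f <= f_hi]
    if len(f) < 10:
        raise ValueError(f"only {len(f)} frequencies in the fit window; need >= 10")
    return 1.0 + len(f) / float(np.log(f / f_lo).sum())


def fingerprint_decay(
    rep: Repertoire,
    M: int,
    params: DynamicsParams,
    times: Sequence[float],
    gamma: float = DEFAULT_GAMMA,
) -> list[tuple[float, float, float]]:
    """Expected S and I between an initial sample and a later one, over time.

    An initial sample of ``M`` cells is drawn by frequency; the captured
    clones' frequencies are then evolved, and at each requested time t the
    expected sharing with a fresh size-M sample is

        ⟨S⟩(t) = Σ_s (1 − (1 − f(s, t))^M)

    over the initially captured clones (extinct ones contribute 0), and
    ⟨I⟩(t) weights each term by ln(1/pgen(s)) − γ (NaN when the repertoire
    carries no pgen values).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    times = list(times)
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    if sorted(times) != times:
        raise ValueError("times must be non-decreasing")
    rng = np.random.default_rng(params.seed)

    freqs = rep.frequencies
    sample_counts = rng.multinomial(M, freqs / freqs.sum())
    captured = sample_counts > 0
    f0 = freqs[captured]
    pgen = rep.pgen[captured]
    usable = np.isfinite(pgen) & (pgen > 0)
    w = np.where(usable, -np.log(np.where(usable, pgen, 1.0)) - gamma, 0.0)
    have_pgen = bool(usable.any())

    x = np.log(f0)
    alive = np.ones(len(x), dtype=bool)
    out = []
    t_prev = 0.0
    for t in times:
        x, alive = _evolve_x(x, params, t - t_prev, rng, alive)
        t_prev = t
        f = np.where(alive, np.exp(np.minimum(x, 0.0)), 0.0)
        with np.errstate(divide="ignore"):  # f = 1 -> capture probability 1
            capture = -np.expm1(M * np.log1p(-np.minimum(f, 1.0)))
        S = float(capture.sum())
        I = float((capture * w)[usable].sum()) if have_pgen else float("nan")
        out.append((t, S, I))
    return out
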