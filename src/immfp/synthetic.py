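"""Synthetic repertoires with the statistical structure the method assumes.

An individual is modeled as ``n_clones`` clones whose frequencies follow a
truncated power law ρ(f) ∝ f^−α (inverse-CDF sampling, then normalization)
and whose CDR3 sequences are drawn from a generative recombination model
*independently* of their frequencies — the independence of clone size and
generation probability is an assumption of the scoring model that holds in
real repertoires. Convergent sharing between unrelated individuals arises
naturally because all individuals draw sequences from the same generative
model: high-P_gen sequences recur across individuals.

Scale choices: ``n_clones`` defaults to 10^4 (not the biological 10^8-10^10)
with ``f_min`` raised to 1e-6 accordingly. What matters to the method is the
structure — a heavy-tailed clone-size law combined with a many-decade P_gen
spread — not the absolute numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, _evolve_x
from .pgen import ToyRecombinationModel, default_toy_model
from .repertoire import KEY_CDR3, Repertoire, downsample
from .scores import PowerLawPrior

__all__ = [
    "SyntheticConfig",
    "sample_power_law_frequencies",
    "generate_repertoire",
    "generate_pair",
    "generate_longitudinal",
]

SCENARIOS = ("autologous", "heterologous", "twin-like")

#: Desk-scale default clone-size prior (f_min raised to suit 10^4 clones).
DEFAULT_SYNTHETIC_PRIOR = PowerLawPrior(alpha=2.0, f_min=1e-6, f_max=0.01, q=1.0)


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic individual or pair of individuals."""

    n_clones: int = 10000
    prior: PowerLawPrior = DEFAULT_SYNTHETIC_PRIOR
    pgen_model: ToyRecombinationModel = field(default_factory=default_toy_model)
    seed: int = 0
    scenario: str = "autologous"
    twin_share_fraction: float = 0.05

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0 <= self.twin_share_fraction <= 1:
            raise ValueError("twin_share_fraction must lie in [0, 1]")


def sample_power_law_frequencies(
    prior: PowerLawPrior, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n raw frequencies from the truncated power law by inverse CDF.

    The draws follow ρ(f) ∝ f^−α on [f_min, f_max] exactly; they are *not*
    normalized to sum to 1 (callers normalize when building a repertoire).
    """
    u = rng.random(n)
    a, b, alpha = prior.f_min, prior.f_max, prior.alpha
    e = 1.0 - alpha
    return (a**e + u * (b**e - a**e)) ** (1.0 / e)


def generate_repertoire(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
) -> Repertoire:
    """One synthetic individual: frequency-only repertoire with exact pgen.

    Within-individual sequence collisions (the same CDR3 generated for two
    clones) are merged into a single clonotype with the summed frequency.
    Deterministic for a given (config, seed).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = sample_power_law_frequencies(config.prior, config.n_clones, rng)
    seqs, pgen = config.pgen_model.sample(config.n_clones, rng)
    tbl = pd.DataFrame({"cdr3_nt": seqs, "frequency": freqs, "pgen": pgen})
    tbl = tbl.groupby("cdr3_nt", as_index=False).agg(
        frequency=("frequency", "sum"), pgen=("pgen", "first")
    )
    tbl["frequency"] = tbl["frequency"] / tbl["frequency"].sum()
    return Repertoire(
        tbl,
        sample_id=sample_id,
        chain="TRB",
        key_fields=KEY_CDR3,
        metadata={"synthetic": True, "n_clones_drawn": config.n_clones},
    )


def generate_pair(
    config: SyntheticConfig, M1: int, M2: int
) -> tuple[Repertoire, Repertoire, str]:
    """A labeled pair of samples under the configured scenario.

    * ``autologous``: two independent downsamples of one individual.
    * ``heterologous``: downsamples of two independently generated
      individuals sharing the same generative model (convergent sharing of
      high-P_gen sequences arises naturally).
    * ``twin-like``: as heterologous, but a fraction of the second
      individual's clones is copied from the first, emulating the elevated
      (yet still small) sharing of identical twins.
    """
    rng = np.random.default_rng(config.seed)
    if config.scenario == "autologous":
        rep = generate_repertoire(config, rng, sample_id="ind1")
        return downsample(rep, M1, rng), downsample(rep, M2, rng), "autologous"

    rep1 = generate_repertoire(config, rng, sample_id="ind1")
    rep2 = generate_repertoire(config, rng, sample_id="ind2")
    if config.scenario == "twin-like":
        k = int(round(config.twin_share_fraction * len(rep2)))
        if k > 0:
            donor = rep1.table.sample(n=min(k, len(rep1)), random_state=rng.integers(2**31))
            recipient = rep2.table.sample(n=len(rep2) - len(donor), random_state=rng.integers(2**31))
            tbl = pd.concat([recipient, donor], ignore_index=True)
            tbl = tbl.groupby("cdr3_nt", as_index=False).agg(
                frequency=("frequency", "sum"), pgen=("pgen", "first")
            )
            tbl["frequency"] = tbl["frequency"] / tbl["frequency"].sum()
            rep2 = Repertoire(
                tbl, sample_id="ind2-twin", chain="TRB", key_fields=KEY_CDR3,
                metadata={"synthetic": True, "twin_share_fraction": config.twin_share_fraction},
            )
    return (
        downsample(rep1, M1, rng),
        downsample(rep2, M2, rng),
        config.scenario,
    )


def generate_longitudinal(
    config: SyntheticConfig,
    M: int,
    params: DynamicsParams,
    times: Sequence[float],
) -> list[Repertoire]:
    """Samples of M cells from one individual whose clones turn over in time.

    The underlying repertoire evolves under the fluctuating-growth-rate
    dynamics (frequencies unnormalized during evolution, renormalized at
    each sampling time, extinct clones dropped); a fresh size-M sample is
    drawn at each requested time. Deterministic per (config, params, seed).
    """
    times = list(times)
    if sorted(times) != times or (times and times[0] < 0):
        raise ValueError("times must be non-negative and non-decreasing")
    rng = np.random.default_rng(config.seed)
    rep = generate_repertoire(config, rng, sample_id="ind1")
    x = np.log(rep.frequencies)
    alive = np.ones(len(x), dtype=bool)
    out = []
    t_prev = 0.0
    for t in times:
        x, alive = _evolve_x(x, params, t - t_prev, rng, alive)
        t_prev = t
        tbl = rep.table.loc[alive, ["cdr3_nt", "pgen"]].copy()
        f = np.exp(x[alive])
        tbl["frequency"] = f / f.sum()
        current = Repertoire(
            tbl, sample_id=f"{rep.sample_id}|t={t:g}", chain="TRB",
            key_fields=KEY_CDR3, metadata={"synthetic": True, "time": t},
        )
        out.append(downsample(current, M, rng))
    return out
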