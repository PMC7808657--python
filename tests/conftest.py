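"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from immfp import Repertoire, SyntheticConfig, ToyRecombinationModel, downsample
from immfp.synthetic import generate_repertoire


# ---------------------------------------------------------------------------
# independent oracles (never call the code paths they check)

def g_by_enumeration(N: int, M: int, n: int) -> float:
    """P(an M-subset of N reads misses all n tagged reads), by exhaustive enumeration."""
    tagged = set(range(n))
    hits = sum(
        1 for subset in itertools.combinations(range(N), M) if tagged.isdisjoint(subset)
    )
    return hits / comb(N, M)


def binom_pmf(N: int, n: int, f: float) -> float:
    return comb(N, n) * f**n * (1.0 - f) ** (N - n)


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def tiny_model() -> ToyRecombinationModel:
    """Two V tails, two J heads: small enough for exhaustive enumeration."""
    return ToyRecombinationModel(
        v_tails=("AA", "CC"),
        v_probs=(0.6, 0.4),
        j_heads=("GG", "TT"),
        j_probs=(0.7, 0.3),
        p_ins=0.5,
    )


@pytest.fixture(scope="session")
def truth_rep() -> Repertoire:
    """A default-scale synthetic individual (frequency-only, exact pgen)."""
    return generate_repertoire(SyntheticConfig(seed=11), np.random.default_rng(11))


@pytest.fixture(scope="session")
def deep_rep(truth_rep) -> Repertoire:
    """A deep observed dataset (200k reads) from the synthetic individual."""
    return downsample(truth_rep, 200_000, np.random.default_rng(12))


@pytest.fixture
def make_tsv(tmp_path):
    """Write a clonotype table to a temp TSV and return the path."""

    def _write(rows: list[dict], name: str = "rep.tsv", columns=None, sep="\t"):
        path = tmp_path / name
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(path, sep=sep, index=False)
        return path

    return _write
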