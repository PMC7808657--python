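"""Generation probabilities for receptor sequences.

The probability P_gen(s) that V(D)J recombination produces a given CDR3
nucleotide sequence spans many orders of magnitude and is the quantity that
separates "public" sequences (likely to appear in several individuals) from
essentially private ones. Three providers are available:

* :class:`ColumnPgenProvider` — pass through values precomputed elsewhere
  (e.g. with OLGA) and stored in the input table;
* :class:`ToyRecombinationModel` — a self-contained generative model with
  exactly computable P_gen, used for synthetic data and tests;
* :class:`ExternalBackend` — shells out to a user-installed engine.

The toy model concatenates a V tail, a geometric-length nucleotide insertion
and a J head. The V tails all have the same length (hence form a prefix-free
set) and the J heads form a suffix-free set, so every generable sequence has
exactly one (V, insertion, J) decomposition and its P_gen is an exact finite
product — no summation over recombination scenarios is needed, unlike for
real TRB models.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, Protocol, Sequence, runtime_checkable

import numpy as np

from .exceptions import ConfigurationError, MissingPgenError
from .repertoire import Repertoire

_NT = "ACGT"


@runtime_checkable
class PgenProvider(Protocol):
    """Anything that can evaluate P_gen for a batch of CDR3 sequences."""

    def pgen_many(self, seqs: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class ToyRecombinationModel:
    """Prefix-free toy generative model with exact, product-form P_gen.

    Parameters
    ----------
    v_tails, v_probs
        V-segment 3' tails and their usage probabilities (sum to 1). All
        tails must have equal length so the set is prefix-free.
    j_heads, j_probs
        J-segment 5' heads and usage probabilities; the set must be
        suffix-free (no head is a suffix of another).
    p_ins
        Stop probability of the geometric insertion-length law:
        P(L = l) = p_ins * (1 - p_ins)**l for l >= 0.
    nt_probs
        Probabilities of A, C, G, T at each inserted position.
    """

    v_tails: tuple[str, ...]
    v_probs: tuple[float, ...]
    j_heads: tuple[str, ...]
    j_probs: tuple[float, ...]
    p_ins: float = 0.25
    nt_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if len(self.v_tails) != len(self.v_probs) or len(self.j_heads) != len(self.j_probs):
            raise ValueError("segment and probability lists must have equal lengths")
        for probs, what in ((self.v_probs, "v_probs"), (self.j_probs, "j_probs"), (self.nt_probs, "nt_probs")):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{what} must be non-negative and sum to 1")
        if not 0 < self.p_ins <= 1:
            raise ValueError("p_ins must lie in (0, 1]")
        if len({len(v) for v in self.v_tails}) != 1:
            raise ValueError("v_tails must all have the same length (prefix-free set)")
        if len(set(self.v_tails)) != len(self.v_tails):
            raise ValueError("v_tails must be distinct")
        for a in self.j_heads:
            for b in self.j_heads:
                if a != b and a.endswith(b):
                    raise ValueError(f"j_heads must be suffix-free; {b!r} is a suffix of {a!r}")
        if len(set(self.j_heads)) != len(self.j_heads):
            raise ValueError("j_heads must be distinct")

    # -- exact evaluation --------------------------------------------------

    def decompose(self, seq: str) -> tuple[str, str, str] | None:
        """Return the unique (v_tail, insertion, j_head) decomposition, or None."""
        Lv = len(self.v_tails[0])
        v = seq[:Lv]
        if v not in self.v_tails:
            return None
        j = next((h for h in self.j_heads if seq.endswith(h)), None)
        if j is None or Lv + len(j) > len(seq):
            return None
        ins = seq[Lv : len(seq) - len(j)]
        if any(c not in _NT for c in ins):
            return None
        return v, ins, j

    def pgen(self, seq: str) -> float:
        """Exact generation probability; 0 for sequences the model cannot produce."""
        dec = self.decompose(seq)
        if dec is None:
            return 0.0
        v, ins, j = dec
        p = self.v_probs[self.v_tails.index(v)] * self.j_probs[self.j_heads.index(j)]
        p *= self.p_ins * (1.0 - self.p_ins) ** len(ins)
        for c in ins:
            p *= self.nt_probs[_NT.index(c)]
        return p

    def pgen_many(self, seqs: Sequence[str]) -> np.ndarray:
        return np.array([self.pgen(s) for s in seqs], dtype=float)

    def enumerate_sequences(self, max_insertions: int) -> Iterator[tuple[str, float]]:
        """Yield every (sequence, pgen) with insertion length <= max_insertions.

        The total probability enumerated is 1 - (1 - p_ins)**(max_insertions + 1),
        i.e. all mass except the geometric tail beyond the length cutoff.
        """
        for li in range(max_insertions + 1):
            for ins in product(_NT, repeat=li):
                for v in self.v_tails:
                    for j in self.j_heads:
                        seq = v + "".join(ins) + j
                        yield seq, self.pgen(seq)

    # -- sampling ----------------------------------------------------------

    def sample(
        self, n: int, seed: int | np.random.Generator = 0
    ) -> tuple[list[str], np.ndarray]:
        """Draw n i.i.d. sequences from the generative law, with exact pgen.

        Returned pgen values equal :meth:`pgen` on the same sequences exactly
        (the decomposition is unique, so the sampled scenario is the only one).
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vi = rng.choice(len(self.v_tails), size=n, p=np.asarray(self.v_probs))
        ji = rng.choice(len(self.j_heads), size=n, p=np.asarray(self.j_probs))
        lens = rng.geometric(self.p_ins, size=n) - 1  # support {0, 1, ...}
        total = int(lens.sum())
        flat = rng.choice(4, size=total, p=np.asarray(self.nt_probs))
        bounds = np.concatenate([[0], np.cumsum(lens)])
        nt = np.array(list(_NT))
        seqs = []
        for k in range(n):
            ins = "".join(nt[flat[bounds[k] : bounds[k + 1]]])
            seqs.append(self.v_tails[vi[k]] + ins + self.j_heads[ji[k]])
        # evaluate through the same product as pgen() so values match it exactly
        return seqs, self.pgen_many(seqs)


def default_toy_model() -> ToyRecombinationModel:
    """Default toy model: 16 V tails (6 nt), 12 suffix-free J heads (6-9 nt).

    Segment usage follows a geometric profile (ratio 3/4) so that, combined
    with the geometric insertion law, log10 P_gen spans well over six orders
    of magnitude across draws — a scaled-down analogue of the enormous
    spread of real V(D)J generation probabilities.
    """
    v_tails = (
        "AAAAAG", "AGTAGA", "ATCGAC", "CAGCCC", "CCGCGG", "CCGCTC", "CCGTCA",
        "GATCAT", "GGAAAG", "GGAACC", "GGCTGC", "GGGTGT", "GGTCTC", "GTGATT",
        "TCGTCC", "TTGGCT",
    )
    j_heads = (
        "AAAGCC", "GAGGAAC", "CTCGATAT", "CCCGCACTC", "GCTCGA", "GCGAGTC",
        "AATGACTC", "GTATTCACA", "CGTGAG", "AATAGGT", "ATTGCCGG", "CGACACATT",
    )
    vw = 0.75 ** np.arange(len(v_tails))
    jw = 0.75 ** np.arange(len(j_heads))
    return ToyRecombinationModel(
        v_tails=v_tails,
        v_probs=tuple(vw / vw.sum()),
        j_heads=j_heads,
        j_probs=tuple(jw / jw.sum()),
        p_ins=0.25,
    )


@dataclass
class ColumnPgenProvider:
    """Pass through pgen values already present in the repertoire table."""

    def pgen_many(self, seqs: Sequence[str]) -> np.ndarray:  # pragma: no cover - trivial
        raise ConfigurationError(
            "ColumnPgenProvider reads values from the table; use annotate_pgen(rep, provider)"
        )


@dataclass
class ExternalBackend:
    """Invoke a user-installed generation-probability engine.

    The command receives one sequence per line on a file passed as last
    argument and must print tab-separated ``sequence<TAB>pgen`` lines. This
    matches the command-line contract of common engines (e.g.
    ``olga-compute_pgen --humanTRB -i <file>``). Disabled unless the
    executable is present.
    """

    command: tuple[str, ...] = ("olga-compute_pgen", "--humanTRB", "-i")

    def pgen_many(self, seqs: Sequence[str]) -> np.ndarray:
        exe = self.command[0]
        if shutil.which(exe) is None:
            raise ConfigurationError(
                f"external pgen backend {exe!r} not found on PATH; install it or use "
                "the precomputed-column or toy-model providers"
            )
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
            fh.write("\n".join(seqs) + "\n")
            name = fh.name
        out = subprocess.run(
            [*self.command, name], capture_output=True, text=True, check=True
        ).stdout
        values = {}
        for line in out.splitlines():
            parts = line.split("\t")
            if len(parts) >= 2:
                try:
                    values[parts[0]] = float(parts[1])
                except ValueError:
                    continue
        return np.array([values.get(s, 0.0) for s in seqs], dtype=float)


def annotate_pgen(rep: Repertoire, provider: PgenProvider | ColumnPgenProvider) -> Repertoire:
    """Attach generation probabilities to every clonotype.

    Sequences the provider cannot evaluate are assigned pgen = 0 and counted
    in ``metadata['n_pgen_unevaluable']``; downstream, such clonotypes are
    excluded from the I score (they still count toward S).
    """
    if isinstance(provider, ColumnPgenProvider):
        if rep.table["pgen"].isna().all() and len(rep):
            raise MissingPgenError(
                "input table has no pgen column values; supply them or use a model provider"
            )
        return rep
    values = provider.pgen_many(list(rep.table["cdr3_nt"]))
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError("provider returned pgen outside [0, 1]")
    tbl = rep.table.copy()
    tbl["pgen"] = values
    if not rep.has_counts and len(tbl):
        tbl = tbl.drop(columns=["count"])
    n_zero = int((values == 0).sum())
    return rep.with_table(tbl, n_pgen_unevaluable=n_zero)


def paired_pgen(pgen_alpha: float, pgen_beta: float) -> float:
    """Generation probability of a paired αβ receptor.

    The two chains recombine independently, so the probability of generating
    the pair is the product of the single-chain probabilities.
    """
    a, b = np.asarray(pgen_alpha, dtype=float), np.asarray(pgen_beta, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("generation probabilities must lie in [0, 1]")
    out = a * b
    return float(out) if out.ndim == 0 else out
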