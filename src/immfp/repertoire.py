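"""Clonotype tables and the in-memory repertoire container.

A repertoire is a collection of unique clonotypes from one sample. Each
clonotype is identified by a *sharing key* — by convention the CDR3
nucleotide sequence together with the V and J gene calls when those are
available, the CDR3 alone otherwise. Rows with identical keys are aggregated
by summing their abundances, so keys are unique within a repertoire.

Two kinds of repertoires are supported:

* **observed** repertoires carry integer read/cell counts ``n(s)`` with
  ``frequency = n(s) / N`` where ``N`` is the total;
* **frequency-only** repertoires (e.g. the true clone-size composition of a
  synthetic individual) carry normalized frequencies but no counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .exceptions import SchemaError

log = logging.getLogger(__name__)

#: Canonical column order of clonotype tables.
CANONICAL_COLUMNS = ("cdr3_nt", "v_gene", "j_gene", "count", "frequency", "pgen")

#: Sharing-key conventions.
KEY_CDR3 = ("cdr3_nt",)
KEY_CDR3_VJ = ("cdr3_nt", "v_gene", "j_gene")

_NT_RE = re.compile(r"^[ACGT]+$")

#: Tolerance on Σ frequency = 1.
_FREQ_TOL = 1e-9


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate an in-frame CDR3 nucleotide string to amino acids.

    The conventional CDR3 extraction (from the conserved cysteine to the
    F/W anchor) yields sequences that are in frame starting at position 0.
    """
    if len(cdr3_nt) % 3 != 0:
        raise ValueError(f"CDR3 length {len(cdr3_nt)} is not a multiple of 3")
    return str(Seq(cdr3_nt).translate())


@dataclass(frozen=True)
class Clonotype:
    """One unique receptor with its abundance and optional generation probability."""

    cdr3_nt: str
    v_gene: str = ""
    j_gene: str = ""
    count: int | None = None
    frequency: float | None = None
    pgen: float | None = None

    @property
    def cdr3_aa(self) -> str:
        return translate_cdr3(self.cdr3_nt)


class Repertoire:
    """A collection of unique clonotypes from one sample.

    Parameters
    ----------
    table
        Clonotype table with at least a ``cdr3_nt`` column and either a
        ``count`` or a ``frequency`` column. Extra columns are dropped.
    sample_id
        Identifier carried through to output tables.
    chain
        Receptor chain, one of ``{"TRB", "TRA", "IGH", "paired"}``.
    key_fields
        Sharing-key convention; defaults to CDR3+V+J restricted to the
        columns actually present.
    metadata
        Free-form key/value annotations (e.g. filtering statistics).

    The constructor validates, aggregates rows with identical sharing keys
    (counts and frequencies summed, pgen taken from the first row), and sorts
    by key so that equal repertoires have byte-identical tables.
    """

    CHAINS = ("TRB", "TRA", "IGH", "paired")

    def __init__(
        self,
        table: pd.DataFrame,
        sample_id: str = "",
        chain: str = "TRB",
        key_fields: Sequence[str] | None = None,
        metadata: Mapping | None = None,
    ):
        if chain not in self.CHAINS:
            raise ValueError(f"unknown chain {chain!r}; expected one of {self.CHAINS}")
        if "cdr3_nt" not in table.columns:
            raise SchemaError("clonotype table lacks a 'cdr3_nt' column")
        if "count" not in table.columns and "frequency" not in table.columns:
            raise SchemaError("clonotype table needs a 'count' or 'frequency' column")

        tbl = table.copy()
        for col in ("v_gene", "j_gene"):
            if col not in tbl.columns:
                tbl[col] = ""
            tbl[col] = tbl[col].fillna("").astype(str)
        if "pgen" not in tbl.columns:
            tbl["pgen"] = np.nan
        tbl["cdr3_nt"] = tbl["cdr3_nt"].astype(str)

        has_counts = "count" in tbl.columns and tbl["count"].notna().all() and len(tbl)
        if "count" not in tbl.columns:
            tbl["count"] = np.nan

        if key_fields is None:
            key_fields = KEY_CDR3_VJ if (tbl["v_gene"] != "").any() or (tbl["j_gene"] != "").any() else KEY_CDR3
        self.key_fields = tuple(key_fields)

        # Aggregate duplicate sharing keys (sum abundances, keep first pgen).
        agg: dict = {"pgen": "first"}
        agg["count"] = "sum"
        if "frequency" in tbl.columns:
            agg["frequency"] = "sum"
        for col in ("cdr3_nt", "v_gene", "j_gene"):
            if col not in self.key_fields:
                agg.setdefault(col, "first")
        tbl = (
            tbl.groupby(list(self.key_fields), as_index=False, sort=True)
            .agg(agg)
            .sort_values(list(self.key_fields), kind="mergesort", ignore_index=True)
        )

        if has_counts:
            counts = tbl["count"].to_numpy(dtype=float)
            if len(counts) and np.any(counts < 1):
                raise ValueError("clonotype counts must be >= 1")
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("clonotype counts must be integers")
            tbl["count"] = counts.astype(np.int64)
            total = int(tbl["count"].sum())
            tbl["frequency"] = tbl["count"] / total if total > 0 else 0.0
        else:
            tbl["count"] = np.nan
            if "frequency" not in tbl.columns:
                if len(tbl):
                    raise ValueError("clonotype counts contain missing values")
                tbl["frequency"] = np.nan
            freq = tbl["frequency"].to_numpy(dtype=float)
            if len(freq):
                if np.any(freq <= 0) or np.any(freq > 1):
                    raise ValueError("frequencies must lie in (0, 1]")
                s = freq.sum()
                if abs(s - 1.0) > _FREQ_TOL:
                    raise ValueError(f"frequencies sum to {s:.6g}, expected 1")
                tbl["frequency"] = freq / s  # exact renormalization within tolerance

        cols = [c for c in CANONICAL_COLUMNS if c != "sample_id"]
        self.table = tbl[list(cols)].reset_index(drop=True)
        self.sample_id = sample_id
        self.chain = chain
        self.metadata = dict(metadata or {})

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterator[Clonotype]:
        for row in self.table.itertuples(index=False):
            yield Clonotype(
                cdr3_nt=row.cdr3_nt,
                v_gene=row.v_gene,
                j_gene=row.j_gene,
                count=None if pd.isna(row.count) else int(row.count),
                frequency=row.frequency,
                pgen=None if pd.isna(row.pgen) else float(row.pgen),
            )

    def __repr__(self) -> str:
        return (
            f"Repertoire({self.sample_id!r}, chain={self.chain}, "
            f"{len(self)} clonotypes, N={self.total_reads})"
        )

    @property
    def has_counts(self) -> bool:
        return len(self.table) > 0 and self.table["count"].notna().all()

    @property
    def total_reads(self) -> int | None:
        """Total number of reads/cells N, or None for frequency-only repertoires."""
        if not self.has_counts:
            return None if len(self.table) else 0
        return int(self.table["count"].sum())

    @property
    def counts(self) -> np.ndarray:
        if not self.has_counts and len(self.table):
            raise ValueError("repertoire carries frequencies only, no counts")
        return self.table["count"].to_numpy(dtype=np.int64) if len(self.table) else np.array([], dtype=np.int64)

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy(dtype=float)

    @property
    def pgen(self) -> np.ndarray:
        return self.table["pgen"].to_numpy(dtype=float)

    @property
    def keys(self) -> pd.Index:
        """Sharing keys as strings, '|'-joined over the key fields."""
        if len(self.table) == 0:
            return pd.Index([], dtype=object)
        parts = [self.table[f].astype(str) for f in self.key_fields]
        joined = parts[0]
        for p in parts[1:]:
            joined = joined.str.cat(p, sep="|")
        return pd.Index(joined)

    def with_table(self, table: pd.DataFrame, **meta_updates) -> "Repertoire":
        """Return a new repertoire with a replacement table, keeping identity fields."""
        md = dict(self.metadata)
        md.update(meta_updates)
        return Repertoire(
            table,
            sample_id=self.sample_id,
            chain=self.chain,
            key_fields=self.key_fields,
            metadata=md,
        )


def downsample(rep: Repertoire, M: int, seed: int | np.random.Generator = 0) -> Repertoire:
    """Draw ``M`` cells from a repertoire according to clonotype frequencies.

    Cells are drawn multinomially on the empirical frequencies, mimicking the
    sampling of a small number of cells from blood (valid because M is far
    smaller than the number of cells in the body). The returned repertoire has
    integer counts summing to exactly ``M``. Identical seeds give identical
    results.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    if len(rep) == 0:
        raise ValueError("cannot downsample an empty repertoire")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rep.frequencies
    counts = rng.multinomial(M, freqs / freqs.sum())
    keep = counts > 0
    tbl = rep.table.loc[keep, ["cdr3_nt", "v_gene", "j_gene", "pgen"]].copy()
    tbl["count"] = counts[keep]
    out = rep.with_table(tbl)
    out.sample_id = f"{rep.sample_id}|M={M}" if rep.sample_id else f"M={M}"
    return out


def filter_productive(rep: Repertoire, pseudogenes: set[str] | None = None) -> Repertoire:
    """Remove non-productive clonotypes and renormalize.

    A clonotype is dropped when its CDR3 nucleotide length is not a multiple
    of three (out of frame), when its in-frame translation contains a stop
    codon, or when its V gene appears in the supplied pseudogene list. When no
    pseudogene list is given, the V-gene criterion is skipped (with a logged
    notice), since gene functionality calls depend on the reference used.
    """
    if len(rep) == 0:
        return rep.with_table(rep.table, n_nonproductive_dropped=0)
    seqs = rep.table["cdr3_nt"]
    in_frame = (seqs.str.len() % 3 == 0).to_numpy()
    no_stop = np.array(
        [("*" not in translate_cdr3(s)) if ok else False for s, ok in zip(seqs, in_frame)]
    )
    keep = in_frame & no_stop
    if pseudogenes:
        keep &= ~rep.table["v_gene"].isin(pseudogenes).to_numpy()
    else:
        log.info("no pseudogene list supplied; skipping the non-functional V-gene filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("filter_productive: dropped %d non-productive clonotypes", n_dropped)
    tbl = rep.table.loc[keep].copy()
    if not rep.has_counts and len(tbl):
        tbl["frequency"] = tbl["frequency"] / tbl["frequency"].sum()
        tbl = tbl.drop(columns=["count"])
    return rep.with_table(tbl, n_nonproductive_dropped=n_dropped)
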