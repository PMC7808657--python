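"""Reading and writing clonotype tables.

Supports a generic delimited format with a configurable column map plus
presets for the two common bulk RepSeq table dialects (immunoSEQ-style and
MiXCR-style headers). Tables may be TSV or CSV, optionally gzip-compressed.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .repertoire import Repertoire

log = logging.getLogger(__name__)

_NT_RE = re.compile(r"^[ACGT]+$")

#: Column-name presets, mapping file columns to canonical names.
FORMATS: dict[str, dict[str, str]] = {
    "generic": {
        "cdr3_nt": "cdr3_nt",
        "count": "count",
        "v_gene": "v_gene",
        "j_gene": "j_gene",
        "pgen": "pgen",
        "frequency": "frequency",
    },
    "immunoseq": {
        "nucleotide": "cdr3_nt",
        "templates": "count",
        "vGeneName": "v_gene",
        "jGeneName": "j_gene",
    },
    "mixcr": {
        "nSeqCDR3": "cdr3_nt",
        "cloneCount": "count",
        "bestVGene": "v_gene",
        "bestJGene": "j_gene",
    },
}


def _separator(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    return "," if name.endswith(".csv") else "\t"


def read_repertoire(
    path: str | Path,
    format: str = "generic",
    column_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    chain: str = "TRB",
    key_fields: tuple[str, ...] | None = None,
) -> Repertoire:
    """Read, validate and aggregate a clonotype table.

    Parameters
    ----------
    path
        TSV or CSV file (``.gz`` accepted). The delimiter is inferred from
        the file name.
    format
        One of ``"generic"``, ``"immunoseq"``, ``"mixcr"``.
    column_map
        Extra ``{file column: canonical column}`` entries overriding the
        preset; canonical columns are ``cdr3_nt``, ``count``, ``v_gene``,
        ``j_gene``, ``pgen``, ``frequency``.

    Rows whose CDR3 is not a pure A/C/G/T string, and rows with missing or
    non-positive counts, are dropped with a logged warning. A file without a
    resolvable CDR3 or abundance column raises :class:`SchemaError`.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(FORMATS)}")
    mapping = dict(FORMATS[format])
    if column_map:
        mapping.update(column_map)

    try:
        raw = pd.read_csv(path, sep=_separator(path), compression="infer", dtype=str)
    except OSError:
        raise
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file has no header row")

    present = {mapping[c]: c for c in raw.columns if c in mapping}
    missing = [c for c in ("cdr3_nt", "count") if c not in present]
    if "count" in missing and "frequency" in present:
        missing.remove("count")
    if missing:
        raise SchemaError(
            f"{path}: cannot resolve mandatory column(s) {missing}; "
            f"columns found: {list(raw.columns)}"
        )

    tbl = pd.DataFrame({canon: raw[src] for canon, src in present.items()})
    n_in = len(tbl)

    ok = tbl["cdr3_nt"].astype(str).str.upper().str.fullmatch(r"[ACGT]+").fillna(False)
    tbl = tbl[ok].copy()
    tbl["cdr3_nt"] = tbl["cdr3_nt"].str.upper()

    if "count" in tbl.columns:
        tbl["count"] = pd.to_numeric(tbl["count"], errors="coerce")
        tbl = tbl[tbl["count"].notna() & (tbl["count"] >= 1)]
    for col in ("pgen", "frequency"):
        if col in tbl.columns:
            tbl[col] = pd.to_numeric(tbl[col], errors="coerce")

    n_dropped = n_in - len(tbl)
    if n_dropped:
        log.warning("%s: dropped %d malformed row(s) of %d", path, n_dropped, n_in)
    if len(tbl) == 0:
        log.warning("%s: no valid clonotypes; returning an empty repertoire", path)

    return Repertoire(
        tbl,
        sample_id=sample_id if sample_id is not None else path.name.removesuffix(".gz").rsplit(".", 1)[0],
        chain=chain,
        key_fields=key_fields,
        metadata={"source": str(path), "n_rows_dropped": n_dropped},
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write the canonical TSV: sample_id, cdr3_nt, v_gene, j_gene, count, frequency, pgen."""
    out = rep.table.copy()
    out.insert(0, "sample_id", rep.sample_id)
    out.to_csv(Path(path), sep="\t", index=False)
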