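"""Readers and writers: expression tables, GMT gene sets, tidy score tables.

All file formats are plain delimited text.  Readers reject malformed input
with errors naming the offending line or field rather than silently coercing
it; parsing itself is delegated to pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import SAMPLE_ID, GeneSet, InputError, validate_expression

log = logging.getLogger("sigscore")

__all__ = [
    "read_expression",
    "read_gmt",
    "write_gmt",
    "write_scores",
    "read_scores",
    "read_labels",
    "GmtRecord",
    "gmt_to_gene_sets",
]

# full round-trip precision for IEEE doubles
_FLOAT_FMT = "%.17g"


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    gene_column: str | None = None,
) -> pd.DataFrame:
    """Read a genes-by-samples expression table and validate it.

    The delimiter defaults to tab (comma for ``.csv``).  The gene-symbol
    column defaults to the first column; pass ``gene_column`` to pick a named
    one.  Duplicate sample headers are rejected before pandas can mangle
    them.  Returns a validated expression matrix (see
    :func:`sigscore.core.validate_expression`).
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    if not header:
        raise InputError(f"{path}: empty file or blank header line")
    fields = header.split(sep)
    sample_fields = fields[1:]
    dups = {f for f in sample_fields if sample_fields.count(f) > 1}
    if dups:
        raise InputError(f"{path}: duplicated sample header(s): {sorted(dups)}")
    try:
        table = pd.read_csv(path, sep=sep, index_col=0 if gene_column is None else None)
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: cannot parse as {sep!r}-delimited text: {exc}") from exc
    if gene_column is not None:
        if gene_column not in table.columns:
            raise InputError(
                f"{path}: gene column {gene_column!r} not found; "
                f"columns are {list(table.columns)}"
            )
        table = table.set_index(gene_column)
    expr = validate_expression(table)
    log.info("read %d genes x %d samples from %s", expr.shape[0], expr.shape[1], path)
    return expr


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GmtRecord:
    """One GMT line: set name, description, gene symbols (deduplicated)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("GMT record needs a non-empty name")
        deduped: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        if not deduped:
            raise InputError(f"GMT record {self.name!r} has no genes")
        object.__setattr__(self, "genes", tuple(deduped))


def read_gmt(path: str | Path) -> list[GmtRecord]:
    """Parse a GMT file: one gene set per line, name TAB description TAB genes."""
    records: list[GmtRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes), got {len(parts)}"
                )
            name, desc, *genes = parts
            genes = [g.strip() for g in genes if g.strip()]
            if not genes:
                raise InputError(f"{path}: line {lineno}: gene set {name!r} is empty")
            records.append(GmtRecord(name.strip(), desc.strip(), tuple(genes)))
    if not records:
        raise InputError(f"{path}: no gene sets found")
    return records


def write_gmt(records: Iterable[GmtRecord | GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT (GeneSet direction is flattened, up then down)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GeneSet):
                rec = GmtRecord(rec.name, "", rec.genes)
            fh.write("\t".join([rec.name, rec.description, *rec.genes]) + "\n")


def gmt_to_gene_sets(records: Iterable[GmtRecord]) -> dict[str, GeneSet]:
    """Convert GMT records to undirected gene sets keyed by name."""
    out: dict[str, GeneSet] = {}
    for rec in records:
        if rec.name in out:
            raise InputError(f"duplicate gene-set name {rec.name!r} in GMT input")
        out[rec.name] = GeneSet(rec.name, rec.genes)
    return out


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------


def write_scores(
    scores: pd.DataFrame,
    path: str | Path,
    layout: str = "wide",
    delimiter: str = "\t",
) -> None:
    """Write a tidy score table as delimited text.

    ``wide`` (default) keeps one row per sample and one column per signature;
    ``long`` melts to ``(sample_id, signature_id, score)`` rows.  NA scores
    are written as the literal token ``NA``; floats carry full round-trip
    precision.
    """
    if SAMPLE_ID not in scores.columns:
        raise InputError(f"score table must contain a {SAMPLE_ID!r} column")
    if layout == "wide":
        out = scores
    elif layout == "long":
        out = scores.melt(id_vars=SAMPLE_ID, var_name="signature_id", value_name="score")
    else:
        raise InputError("layout must be 'wide' or 'long'")
    out.to_csv(path, sep=delimiter, index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_scores(path: str | Path, layout: str = "wide", delimiter: str = "\t") -> pd.DataFrame:
    """Read a score table written by :func:`write_scores` back into wide form.

    The long layout is pivoted back preserving sample order and the order of
    first appearance of each signature.
    """
    table = pd.read_csv(path, sep=delimiter, na_values=["NA"])
    if SAMPLE_ID not in table.columns:
        raise InputError(f"{path}: missing {SAMPLE_ID!r} column")
    if layout == "wide":
        return table
    if layout != "long":
        raise InputError("layout must be 'wide' or 'long'")
    needed = {SAMPLE_ID, "signature_id", "score"}
    if not needed.issubset(table.columns):
        raise InputError(f"{path}: long layout needs columns {sorted(needed)}")
    sample_order = list(pd.unique(table[SAMPLE_ID]))
    sig_order = list(pd.unique(table["signature_id"]))
    wide = table.pivot(index=SAMPLE_ID, columns="signature_id", values="score")
    wide = wide.reindex(index=sample_order, columns=sig_order).reset_index()
    wide.columns.name = None
    return wide


def read_labels(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a two-column (sample, status) label table for the CINSARC classifier."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    table = pd.read_csv(path, sep=sep)
    if table.shape[1] < 2:
        raise InputError(f"{path}: need two columns (sample, status)")
    labels = pd.Series(
        table.iloc[:, 1].to_numpy(), index=table.iloc[:, 0].astype(str).to_numpy()
    )
    if labels.index.has_duplicates:
        raise InputError(f"{path}: duplicated sample identifiers in label table")
    return labels
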