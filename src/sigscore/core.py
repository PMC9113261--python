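"""Core domain types and the expression-matrix contract.

The central in-memory container is a plain :class:`pandas.DataFrame` holding
normalized expression values with **genes as rows** (HUGO symbols in the
index) and **samples as columns**.  ``validate_expression`` enforces the
contract every scoring function relies on: unique gene symbols, unique sample
identifiers, finite values only.  Microarray log-intensities and log-scale
normalized RNA-seq values are both fine — no normalization is performed here.

Gene sets are represented by :class:`GeneSet` (an optionally directional
up/down pair) and bundled signatures by :class:`SignatureDefinition`, which
adds provenance metadata, optional per-gene coefficients and the descriptor of
the original publication's scoring procedure.

Score tables are tidy :class:`pandas.DataFrame` objects: one row per sample, a
``sample_id`` column, and one column per signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("sigscore")

SAMPLE_ID = "sample_id"

#: original-publication scoring procedures a bundled signature may declare
ORIGINAL_METHODS = (
    "mean",
    "weighted_sum",
    "ssgsea_like",
    "dedicated_estimate",
    "dedicated_cinsarc",
    "dedicated_ips",
)

ENRICHMENT_METHODS = ("original", "zscore", "ssgsea", "singscore")


class SigscoreError(Exception):
    """Base class for all package errors."""


class InputError(SigscoreError, ValueError):
    """Malformed or contract-violating input."""


class DegenerateInputError(InputError):
    """Input that is structurally valid but leaves nothing to compute on."""


class UsageError(SigscoreError, ValueError):
    """A disallowed combination of arguments."""


# ---------------------------------------------------------------------------
# gene sets and signatures
# ---------------------------------------------------------------------------


def _clean_symbols(genes: Iterable[str], *, what: str) -> tuple[str, ...]:
    out: list[str] = []
    seen = set()
    for g in genes:
        s = str(g).strip()
        if not s:
            raise InputError(f"{what}: empty gene symbol")
        if s not in seen:  # drop duplicates, keep first occurrence
            seen.add(s)
            out.append(s)
    return tuple(out)


@dataclass(frozen=True)
class GeneSet:
    """A gene set, optionally directional.

    ``up_genes`` must be non-empty; ``down_genes`` may be empty for
    undirected sets.  The two lists are disjoint.
    """

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not str(self.name):
            raise InputError("gene set needs a non-empty name")
        object.__setattr__(self, "up_genes", _clean_symbols(self.up_genes, what=self.name))
        object.__setattr__(self, "down_genes", _clean_symbols(self.down_genes, what=self.name))
        if not self.up_genes:
            raise InputError(f"gene set {self.name!r}: up_genes must be non-empty")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise InputError(
                f"gene set {self.name!r}: up/down lists overlap: {sorted(overlap)}"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        """All genes, up-direction first."""
        return self.up_genes + self.down_genes

    @property
    def directional(self) -> bool:
        return len(self.down_genes) > 0


@dataclass(frozen=True)
class SignatureDefinition:
    """A curated signature: gene set plus provenance and original method."""

    id: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    doi: str = ""
    description: str = ""
    coefficients: Mapping[str, float] | None = None
    original_method: str = "mean"

    def __post_init__(self) -> None:
        if self.original_method not in ORIGINAL_METHODS:
            raise InputError(
                f"signature {self.id!r}: unknown original_method "
                f"{self.original_method!r}; expected one of {ORIGINAL_METHODS}"
            )
        # delegate gene-list validation to GeneSet
        gs = GeneSet(self.id, tuple(self.up_genes), tuple(self.down_genes))
        object.__setattr__(self, "up_genes", gs.up_genes)
        object.__setattr__(self, "down_genes", gs.down_genes)
        object.__setattr__(self, "keywords", tuple(str(k) for k in self.keywords))
        if self.original_method == "weighted_sum":
            coeffs = dict(self.coefficients or {})
            missing = [g for g in gs.genes if g not in coeffs]
            if missing:
                raise InputError(
                    f"signature {self.id!r}: weighted_sum requires a coefficient "
                    f"for every gene; missing {missing}"
                )
            object.__setattr__(self, "coefficients", coeffs)

    @property
    def dedicated(self) -> bool:
        return self.original_method.startswith("dedicated_")

    def gene_set(self) -> GeneSet:
        return GeneSet(self.id, self.up_genes, self.down_genes)


@dataclass
class MethodParams:
    """Options for the single-sample enrichment engines.

    Parameters
    ----------
    method:
        ``original``, ``zscore``, ``ssgsea`` or ``singscore``.
    ssgsea_exponent:
        alpha, the exponent weighting ranks in the ssGSEA running sum
        (default 0.25).
    ssgsea_norm:
        ``raw`` (default) returns the plain enrichment score; ``separate``
        rescales each signature column by its own score range; ``all``
        rescales every score by the global range across all requested
        signatures.
    singscore_center:
        subtract 0.5 from each directional singscore component (default on).
    singscore_undirected_mode:
        how undirected sets are ranked by singscore: ``raw_rank`` treats the
        set as an up-set on plain expression ranks; ``abs_median_centered``
        ranks ``|x - median(sample)|`` instead.
    tie_rule:
        rank tie handling: ``average`` (default), ``min`` or ``max``.
    """

    method: str = "original"
    ssgsea_exponent: float = 0.25
    ssgsea_norm: str = "raw"
    singscore_center: bool = True
    singscore_undirected_mode: str = "raw_rank"
    tie_rule: str = "average"

    def __post_init__(self) -> None:
        if self.method not in ENRICHMENT_METHODS:
            raise UsageError(
                f"method must be one of {ENRICHMENT_METHODS}, got {self.method!r}"
            )
        alpha = float(self.ssgsea_exponent)
        if not np.isfinite(alpha) or alpha < 0:
            raise InputError("ssgsea_exponent must be finite and non-negative")
        self.ssgsea_exponent = alpha
        if self.ssgsea_norm not in ("raw", "separate", "all"):
            raise UsageError("ssgsea_norm must be 'raw', 'separate' or 'all'")
        if self.singscore_undirected_mode not in ("raw_rank", "abs_median_centered"):
            raise UsageError(
                "singscore_undirected_mode must be 'raw_rank' or 'abs_median_centered'"
            )
        if self.tie_rule not in ("average", "min", "max"):
            raise UsageError("tie_rule must be 'average', 'min' or 'max'")


# ---------------------------------------------------------------------------
# expression-matrix validation
# ---------------------------------------------------------------------------


def validate_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes-by-samples expression table.

    Rules applied, in order:

    * gene symbols (the index) are stripped of surrounding whitespace and
      matched case-sensitively (official HUGO symbols are assumed);
    * values are coerced to float; rows containing any missing or non-finite
      value are dropped, with a logged count;
    * duplicate gene symbols are collapsed to the row with the highest mean
      expression (ties keep the first occurrence);
    * sample identifiers must be unique.

    Row order of retained genes and column order are preserved, and the
    function is idempotent: validating a validated matrix returns an equal
    matrix.

    Raises
    ------
    InputError
        on an empty table or duplicate sample identifiers.
    DegenerateInputError
        if every gene row is dropped.
    """
    if not isinstance(table, pd.DataFrame):
        raise InputError("expression input must be a pandas DataFrame")
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise InputError(
            f"expression table must have >=1 gene row and >=1 sample column, "
            f"got shape {table.shape}"
        )
    sample_ids = [str(c) for c in table.columns]
    dup_samples = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
    if len(dup_samples):
        raise InputError(f"duplicate sample identifiers: {sorted(set(dup_samples))}")

    out = table.copy()
    out.columns = sample_ids
    out.index = [str(g).strip() for g in out.index]
    out = out.apply(pd.to_numeric, errors="coerce")
    out = out.astype(float)

    finite = np.isfinite(out.to_numpy())
    keep = finite.all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d gene row(s) with missing/non-finite values", n_dropped)
        out = out.loc[keep]
    if out.shape[0] == 0:
        raise DegenerateInputError("all gene rows dropped during validation")

    if out.index.has_duplicates:
        means = out.mean(axis=1).to_numpy()
        order = np.arange(out.shape[0])
        # keep, per symbol, the row with the highest mean (first on ties)
        best: dict[str, int] = {}
        for pos, sym in zip(order, out.index):
            if sym not in best or means[pos] > means[best[sym]]:
                best[sym] = pos
        keep_pos = sorted(best.values())
        n_collapsed = out.shape[0] - len(keep_pos)
        log.warning("collapsed %d duplicate gene symbol row(s)", n_collapsed)
        out = out.iloc[keep_pos]

    out.index.name = table.index.name or "gene"
    return out


# ---------------------------------------------------------------------------
# tidy score tables
# ---------------------------------------------------------------------------


def score_table(
    sample_ids: Sequence[str], columns: Mapping[str, np.ndarray | Sequence[float]]
) -> pd.DataFrame:
    """Assemble a tidy ScoreTable: ``sample_id`` plus one column per signature."""
    data: dict[str, object] = {SAMPLE_ID: list(sample_ids)}
    for name, values in columns.items():
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(sample_ids),):
            raise InputError(
                f"score column {name!r} has length {arr.shape}, expected {len(sample_ids)}"
            )
        data[str(name)] = arr
    return pd.DataFrame(data)


def coerce_gene_sets(sets: object) -> dict[str, GeneSet]:
    """Normalize user-supplied gene-set collections to ``{name: GeneSet}``.

    Accepts a single :class:`GeneSet` or :class:`SignatureDefinition`, an
    iterable of them, or a mapping ``name -> genes`` where genes may be a
    plain list of symbols, a ``(up, down)`` pair, or a GeneSet.
    """
    if isinstance(sets, (GeneSet, SignatureDefinition)):
        sets = [sets]
    out: dict[str, GeneSet] = {}
    if isinstance(sets, Mapping):
        for name, genes in sets.items():
            if isinstance(genes, GeneSet):
                gs = GeneSet(str(name), genes.up_genes, genes.down_genes)
            elif isinstance(genes, SignatureDefinition):
                gs = GeneSet(str(name), genes.up_genes, genes.down_genes)
            elif (
                isinstance(genes, tuple)
                and len(genes) == 2
                and not isinstance(genes[0], str)
            ):
                gs = GeneSet(str(name), tuple(genes[0]), tuple(genes[1]))
            else:
                gs = GeneSet(str(name), tuple(genes))
            out[gs.name] = gs
    else:
        for item in sets:  # type: ignore[union-attr]
            if isinstance(item, SignatureDefinition):
                gs = item.gene_set()
            elif isinstance(item, GeneSet):
                gs = item
            else:
                raise InputError(
                    "gene-set collections must be GeneSet/SignatureDefinition "
                    "objects or a mapping name -> genes"
                )
            if gs.name in out:
                raise InputError(f"duplicate gene-set name {gs.name!r}")
            out[gs.name] = gs
    if not out:
        raise InputError("no gene sets supplied")
    return out
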