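"""Bundled signature catalog, keyword lookup, coverage checking and dispatch.

The registry ships a small demonstration catalog (each signature a YAML file
under ``sigscore/data/signatures`` with metadata, gene lists and optional
coefficients) plus entries for the three dedicated scorers so that discovery
works through one interface.  User-curated signatures enter through GMT files
or plain gene-set mappings; they are first-class citizens of every function
here.

``hack_sig`` is the front door: it resolves a signature selector (``"all"``,
a list of keywords, or a custom gene-set mapping), picks the scoring engine,
and returns a tidy one-row-per-sample score table.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import dedicated as _ded
from .core import (
    SAMPLE_ID,
    GeneSet,
    InputError,
    MethodParams,
    SignatureDefinition,
    UsageError,
    coerce_gene_sets,
)
from .methods import parallel_score, score_original, score_ssgsea

log = logging.getLogger("sigscore")

__all__ = ["get_sig_info", "get_sig_genes", "check_sig", "hack_sig", "load_registry"]


def _signature_from_yaml(doc: dict) -> SignatureDefinition:
    return SignatureDefinition(
        id=doc["id"],
        up_genes=tuple(doc.get("up_genes", ())),
        down_genes=tuple(doc.get("down_genes", ())),
        keywords=tuple(doc.get("keywords", ())),
        doi=str(doc.get("doi", "") or ""),
        description=str(doc.get("description", "")).strip(),
        coefficients=doc.get("coefficients"),
        original_method=doc.get("original_method", "mean"),
    )


@lru_cache(maxsize=1)
def load_registry() -> dict[str, SignatureDefinition]:
    """All bundled signatures keyed by id, dedicated scorers included."""
    sigs: dict[str, SignatureDefinition] = {}
    sig_dir = resources.files("sigscore.data.signatures")
    for entry in sorted(sig_dir.iterdir(), key=lambda p: p.name):
        if not entry.name.endswith(".yaml"):
            continue
        with entry.open("r") as fh:
            sig = _signature_from_yaml(yaml.safe_load(fh))
        if sig.id in sigs:
            raise InputError(f"duplicate signature id {sig.id!r} in registry")
        sigs[sig.id] = sig

    immune, stroma, _ = _ded.load_estimate_config()
    sigs["estimate_immune"] = SignatureDefinition(
        id="estimate_immune",
        up_genes=immune.up_genes,
        keywords=("estimate", "immune", "purity"),
        doi="10.1038/ncomms3612",
        description="Immune infiltration component of the ESTIMATE tumor-purity method (demo gene list).",
        original_method="dedicated_estimate",
    )
    sigs["estimate_stroma"] = SignatureDefinition(
        id="estimate_stroma",
        up_genes=stroma.up_genes,
        keywords=("estimate", "stroma", "purity"),
        doi="10.1038/ncomms3612",
        description="Stromal component of the ESTIMATE tumor-purity method (demo gene list).",
        original_method="dedicated_estimate",
    )
    cinsarc = _ded.load_cinsarc_genes()
    sigs["cinsarc"] = SignatureDefinition(
        id="cinsarc",
        up_genes=cinsarc.up_genes,
        keywords=("cinsarc", "sarcoma", "metastasis", "risk"),
        doi="10.1038/nm.2174",
        description="CINSARC mitosis/chromosome-integrity signature for nearest-centroid sarcoma risk classification (demo gene list).",
        original_method="dedicated_cinsarc",
    )
    ips_cfg = _ded.load_ips_config()
    ips_genes: list[str] = []
    for m in ips_cfg.markers:
        for g in m.genes:
            if g not in ips_genes:
                ips_genes.append(g)
    sigs["immunophenoscore"] = SignatureDefinition(
        id="immunophenoscore",
        up_genes=tuple(ips_genes),
        keywords=("ips", "immunophenoscore", "immune", "checkpoint"),
        doi="10.1016/j.celrep.2016.12.019",
        description="Immunophenoscore marker panel: MHC, effector-cell, suppressor-cell and checkpoint genes (demo marker lists).",
        original_method="dedicated_ips",
    )
    return sigs


def _all_keywords(sigs: Mapping[str, SignatureDefinition]) -> list[str]:
    kws: set[str] = set()
    for sig in sigs.values():
        kws.add(sig.id)
        kws.update(sig.keywords)
    return sorted(kws)


def _match_signatures(selector: object, exact: bool = False) -> dict[str, SignatureDefinition]:
    sigs = load_registry()
    if isinstance(selector, str) and selector == "all":
        return dict(sorted(sigs.items()))
    if isinstance(selector, str):
        selector = [selector]
    if not isinstance(selector, Sequence) or not all(isinstance(k, str) for k in selector):
        raise InputError("selector must be 'all' or a list of keyword strings")
    matched: dict[str, SignatureDefinition] = {}
    for sid, sig in sigs.items():
        haystack = [sid.lower(), *(k.lower() for k in sig.keywords)]
        for kw in selector:
            k = kw.lower()
            hit = (k in haystack) if exact else any(k in h for h in haystack)
            if hit:
                matched[sid] = sig
                break
    if not matched:
        raise InputError(
            f"no signature matches keyword(s) {list(selector)!r}; "
            f"valid keywords include: {_all_keywords(sigs)}"
        )
    return dict(sorted(matched.items()))


def get_sig_info() -> pd.DataFrame:
    """One row per bundled signature: id, keywords, doi, description."""
    rows = [
        {
            "id": sig.id,
            "keywords": "|".join(sig.keywords),
            "doi": sig.doi,
            "description": sig.description,
            "original_method": sig.original_method,
            "n_genes": len(sig.up_genes) + len(sig.down_genes),
        }
        for sig in load_registry().values()
    ]
    return pd.DataFrame(rows).sort_values("id", ignore_index=True)


def get_sig_genes(selector: object = "all", exact: bool = False) -> dict[str, list[str]]:
    """Gene lists of bundled signatures matching ``selector``.

    ``selector`` is ``"all"`` or a list of keywords matched as
    case-insensitive substrings against signature ids and keywords
    (``exact=True`` switches to whole-keyword matching).
    """
    return {
        sid: list(sig.up_genes + sig.down_genes)
        for sid, sig in _match_signatures(selector, exact=exact).items()
    }


def _resolve_sets(signatures: object, exact: bool) -> tuple[dict[str, GeneSet], dict[str, SignatureDefinition] | None]:
    """Return (gene sets, registry definitions or None for custom input)."""
    is_registry = isinstance(signatures, str) or (
        isinstance(signatures, Sequence)
        and not isinstance(signatures, (GeneSet, SignatureDefinition))
        and all(isinstance(s, str) for s in signatures)
        and len(list(signatures)) > 0
    )
    if is_registry:
        matched = _match_signatures(signatures, exact=exact)
        return {sid: sig.gene_set() for sid, sig in matched.items()}, matched
    return coerce_gene_sets(signatures), None


def check_sig(expr: pd.DataFrame, signatures: object = "all", exact: bool = False) -> pd.DataFrame:
    """Coverage report: how well each signature is represented in ``expr``.

    Works for registry selectors and custom gene-set collections alike.
    Returns one row per signature with the gene count, the number and
    fraction present in the matrix, and the missing symbols.  Zero coverage
    is a valid row, not an error.
    """
    gene_sets, _ = _resolve_sets(signatures, exact)
    present = set(expr.index)
    rows = []
    for name, gs in gene_sets.items():
        genes = gs.genes
        missing = [g for g in genes if g not in present]
        n_present = len(genes) - len(missing)
        rows.append(
            {
                "signature_id": name,
                "n_genes": len(genes),
                "n_present": n_present,
                "frac_present": n_present / len(genes),
                "missing_genes": missing,
            }
        )
    return pd.DataFrame(rows)


def hack_sig(
    expr: pd.DataFrame,
    signatures: object = "all",
    method: str | None = None,
    *,
    ssgsea_exponent: float = 0.25,
    ssgsea_norm: str = "raw",
    singscore_center: bool = True,
    singscore_undirected_mode: str = "raw_rank",
    tie_rule: str = "average",
    n_workers: int = 1,
    exact: bool = False,
) -> pd.DataFrame:
    """Compute signature scores and return a tidy one-row-per-sample table.

    ``signatures`` selects bundled signatures (``"all"`` or keywords) or
    supplies custom gene sets (a mapping name -> genes, or GeneSet objects).
    ``method`` is ``original``, ``zscore``, ``ssgsea`` or ``singscore``; when
    omitted it defaults to each signature's original procedure for registry
    signatures and to raw ssGSEA for custom sets.  Custom sets cannot be
    scored with ``original`` (no publication procedure is attached to them).

    With ``method="original"``, signatures scored by a dedicated procedure
    (ESTIMATE, CINSARC, Immunophenoscore) are skipped with a log message
    pointing at their dedicated functions.
    """
    gene_sets, registry_defs = _resolve_sets(signatures, exact)
    custom = registry_defs is None
    if method is None:
        method = "ssgsea" if custom else "original"
    if custom and method == "original":
        raise UsageError(
            "method='original' needs registry signatures; custom gene sets "
            "carry no original publication procedure"
        )

    params = MethodParams(
        method=method,
        ssgsea_exponent=ssgsea_exponent,
        ssgsea_norm=ssgsea_norm,
        singscore_center=singscore_center,
        singscore_undirected_mode=singscore_undirected_mode,
        tie_rule=tie_rule,
    )

    if method != "original":
        return parallel_score(expr, gene_sets, params, n_workers=n_workers)

    assert registry_defs is not None
    pieces: list[pd.DataFrame] = []
    skipped: list[str] = []
    for sid, sig in registry_defs.items():
        if sig.dedicated:
            skipped.append(sid)
            continue
        if sig.original_method == "ssgsea_like":
            piece = score_ssgsea(
                expr,
                {sid: sig.gene_set()},
                MethodParams(method="ssgsea", ssgsea_exponent=ssgsea_exponent, tie_rule=tie_rule),
            )
        else:
            piece = score_original(expr, sig)
        pieces.append(piece)
    if skipped:
        log.info(
            "skipped dedicated signature(s) %s; use score_estimate / "
            "classify_cinsarc / score_immunophenoscore",
            skipped,
        )
    if not pieces:
        raise UsageError(
            f"selector matched only dedicated signature(s) {skipped}; use "
            "score_estimate / classify_cinsarc / score_immunophenoscore"
        )
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.merge(piece, on=SAMPLE_ID)
    return out
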