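"""Single-sample enrichment engines.

Three generic engines score a gene set independently for every sample of a
normalized expression matrix:

* **combined z-score** — per-gene standardization across samples, then
  ``sum(z) / sqrt(|set|)`` over the set genes;
* **ssGSEA** — a running-sum statistic over the within-sample gene ranking,
  with in-set steps weighted by ``rank**alpha``;
* **singscore** — the normalized mean rank of the set genes within a sample,
  with directional (up/down) handling and optional centering.

``score_original`` evaluates the two archetypes used by original signature
publications (plain mean, coefficient-weighted sum), and ``parallel_score``
fans any engine out over workers with a bit-identical-result guarantee.

Genes listed in a set but absent from the matrix are silently intersected out
here; reporting coverage is the job of ``sigscore.registry.check_sig``.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import rankdata

from .core import (
    SAMPLE_ID,
    DegenerateInputError,
    GeneSet,
    InputError,
    MethodParams,
    SignatureDefinition,
    UsageError,
    coerce_gene_sets,
    score_table,
)

log = logging.getLogger("sigscore")

__all__ = [
    "rank_sample",
    "score_zscore",
    "score_ssgsea",
    "score_singscore",
    "score_original",
    "parallel_score",
    "zscore_matrix",
]


def rank_sample(values: Sequence[float], tie_rule: str = "average") -> np.ndarray:
    """Rank one sample's expression values, 1 = lowest, N = highest.

    Ties are resolved per ``tie_rule`` (``average``, ``min`` or ``max``).
    With the default average rule the rank sum is always ``N(N+1)/2``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DegenerateInputError("ranking needs a 1-D vector of >=2 values")
    if not np.isfinite(arr).all():
        raise InputError("ranking requires finite values")
    if tie_rule not in ("average", "min", "max"):
        raise InputError("tie_rule must be 'average', 'min' or 'max'")
    return rankdata(arr, method=tie_rule).astype(float)


# ---------------------------------------------------------------------------
# combined z-score
# ---------------------------------------------------------------------------


def zscore_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample sd, divisor n-1).

    Genes with zero variance get an all-zero row with a logged warning so a
    constant housekeeping gene cannot abort a run.
    """
    vals = expr.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise DegenerateInputError("z-scoring needs >=2 samples")
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("%d zero-variance gene(s): z-scores set to 0", int(flat.sum()))
        sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def _present_indexer(expr_index: pd.Index, genes: Sequence[str]) -> np.ndarray:
    loc = {g: i for i, g in enumerate(expr_index)}
    return np.array([loc[g] for g in genes if g in loc], dtype=int)


def score_zscore(expr: pd.DataFrame, sets: object) -> pd.DataFrame:
    """Combined z-score per sample: ``sum(z over set) / sqrt(|set & matrix|)``.

    Direction is ignored — the up and down lists of a directional set are
    pooled, as in the classic combined z-score. A set with no genes present
    yields an NA column plus a warning.
    """
    gene_sets = coerce_gene_sets(sets)
    z = zscore_matrix(expr).to_numpy()
    cols: dict[str, np.ndarray] = {}
    for name, gs in gene_sets.items():
        idx = _present_indexer(expr.index, gs.genes)
        if idx.size == 0:
            log.warning("signature %r: no genes present; scores set to NA", name)
            cols[name] = np.full(expr.shape[1], np.nan)
            continue
        cols[name] = z[idx, :].sum(axis=0) / math.sqrt(idx.size)
    return score_table(list(expr.columns), cols)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _ssgsea_sample(
    ranks: np.ndarray, masks: dict[str, np.ndarray], alpha: float
) -> dict[str, float]:
    """Raw ssGSEA enrichment scores for one sample.

    Genes are walked in order of decreasing rank (ties broken by matrix row
    order, stable).  ``P_in`` accumulates normalized ``rank**alpha`` weight
    over in-set genes, ``P_out`` the empirical CDF of out-set genes; the score
    is the summed difference over all positions.
    """
    n = ranks.size
    order = np.argsort(-ranks, kind="stable")
    w = ranks[order] ** alpha
    out: dict[str, float] = {}
    for name, mask in masks.items():
        m = mask[order]
        k = int(m.sum())
        if k == 0:
            out[name] = np.nan
            continue
        if k == n:
            raise InputError(
                f"signature {name!r} covers every gene in the matrix; "
                "ssGSEA needs at least one out-of-set gene"
            )
        win = np.where(m, w, 0.0)
        p_in = np.cumsum(win) / win.sum()
        p_out = np.cumsum(~m) / (n - k)
        out[name] = float((p_in - p_out).sum())
    return out


def score_ssgsea(
    expr: pd.DataFrame, sets: object, params: MethodParams | None = None
) -> pd.DataFrame:
    """ssGSEA scores, one per sample and signature.

    Raw scores by default; ``params.ssgsea_norm`` may rescale each column by
    its own range (``separate``) or all columns by the global range (``all``
    — note this makes scores depend on the cohort *and* on which signatures
    were requested together).
    """
    params = params or MethodParams(method="ssgsea")
    gene_sets = coerce_gene_sets(sets)
    masks = _set_masks(expr.index, gene_sets)
    vals = expr.to_numpy(dtype=float)
    rows = [
        _ssgsea_sample(rank_sample(vals[:, j], params.tie_rule), masks, params.ssgsea_exponent)
        for j in range(vals.shape[1])
    ]
    cols = {
        name: np.array([r[name] for r in rows]) for name in gene_sets
    }
    table = score_table(list(expr.columns), cols)
    return _normalize_ssgsea(table, params.ssgsea_norm)


def _set_masks(expr_index: pd.Index, gene_sets: Mapping[str, GeneSet]) -> dict[str, np.ndarray]:
    masks = {}
    for name, gs in gene_sets.items():
        idx = _present_indexer(expr_index, gs.genes)
        mask = np.zeros(len(expr_index), dtype=bool)
        mask[idx] = True
        if idx.size == 0:
            log.warning("signature %r: no genes present; scores set to NA", name)
        masks[name] = mask
    return masks


def _normalize_ssgsea(table: pd.DataFrame, norm: str) -> pd.DataFrame:
    if norm == "raw":
        return table
    score_cols = [c for c in table.columns if c != SAMPLE_ID]
    if norm == "separate":
        for c in score_cols:
            col = table[c].to_numpy()
            if np.isnan(col).all():
                continue
            rng = np.nanmax(col) - np.nanmin(col)
            if rng == 0:
                raise InputError(
                    f"cannot normalize signature {c!r}: zero score range in this cohort"
                )
            table[c] = col / rng
        return table
    # norm == "all": one global range across every requested signature
    allvals = table[score_cols].to_numpy()
    if np.isnan(allvals).all():
        raise InputError("cannot normalize: all scores are NA")
    rng = np.nanmax(allvals) - np.nanmin(allvals)
    if rng == 0:
        raise InputError("cannot normalize: zero score range across this cohort")
    for c in score_cols:
        table[c] = table[c] / rng
    return table


# ---------------------------------------------------------------------------
# singscore
# ---------------------------------------------------------------------------


def _direction_score(mean_rank: float, n_set: int, n_genes: int) -> float:
    # normalized mean rank: 0 when the set sits at the bottom of the sample's
    # ranking, 1 when it sits at the top
    r_min = (n_set + 1) / 2.0
    r_max = (2 * n_genes - n_set + 1) / 2.0
    if r_max == r_min:
        raise InputError(
            "singscore is undefined for a set spanning every gene in the matrix"
        )
    return (mean_rank - r_min) / (r_max - r_min)


def score_singscore(
    expr: pd.DataFrame, sets: object, params: MethodParams | None = None
) -> pd.DataFrame:
    """singscore: normalized mean rank of set genes within each sample.

    For directional sets the down-component is computed on reversed ranks and
    added to the up-component.  With ``params.singscore_center`` (default) 0.5
    is subtracted from each directional component, so an undirected score lies
    in [-0.5, 0.5] and a bidirectional total in [-1, 1].
    """
    params = params or MethodParams(method="singscore")
    gene_sets = coerce_gene_sets(sets)
    n_genes = expr.shape[0]
    vals = expr.to_numpy(dtype=float)

    up_idx: dict[str, np.ndarray] = {}
    down_idx: dict[str, np.ndarray] = {}
    for name, gs in gene_sets.items():
        up_idx[name] = _present_indexer(expr.index, gs.up_genes)
        down_idx[name] = _present_indexer(expr.index, gs.down_genes)
        if up_idx[name].size == 0:
            log.warning("signature %r: no up genes present; scores set to NA", name)
        if gs.directional and down_idx[name].size == 0 and up_idx[name].size > 0:
            log.warning(
                "signature %r: no down genes present; scoring up-direction only", name
            )

    cols: dict[str, list[float]] = {name: [] for name in gene_sets}
    for j in range(vals.shape[1]):
        col = vals[:, j]
        ranks = rank_sample(col, params.tie_rule)
        alt_ranks: np.ndarray | None = None
        if params.singscore_undirected_mode == "abs_median_centered":
            alt_ranks = rank_sample(np.abs(col - np.median(col)), params.tie_rule)
        rev = n_genes + 1 - ranks
        for name, gs in gene_sets.items():
            iu, idn = up_idx[name], down_idx[name]
            if iu.size == 0:
                cols[name].append(np.nan)
                continue
            use_alt = not gs.directional and alt_ranks is not None
            r_up = (alt_ranks if use_alt else ranks)[iu]
            score = _direction_score(float(r_up.mean()), iu.size, n_genes)
            if params.singscore_center:
                score -= 0.5
            if idn.size:
                down = _direction_score(float(rev[idn].mean()), idn.size, n_genes)
                if params.singscore_center:
                    down -= 0.5
                score += down
            cols[name].append(score)
    return score_table(list(expr.columns), {k: np.array(v) for k, v in cols.items()})


# ---------------------------------------------------------------------------
# original-publication archetypes
# ---------------------------------------------------------------------------


def score_original(expr: pd.DataFrame, sig: SignatureDefinition) -> pd.DataFrame:
    """Score a signature with its original publication's archetype.

    ``mean`` averages expression of the present signature genes per sample;
    ``weighted_sum`` evaluates ``sum(coeff_g * x_gj)`` over present genes
    (absent genes drop their term with a warning — run ``check_sig`` first).
    """
    if sig.original_method not in ("mean", "weighted_sum"):
        raise UsageError(
            f"signature {sig.id!r} declares original_method={sig.original_method!r}; "
            "score_original handles only 'mean' and 'weighted_sum'"
        )
    genes = sig.up_genes + sig.down_genes
    idx = _present_indexer(expr.index, genes)
    if idx.size == 0:
        log.warning("signature %r: no genes present; scores set to NA", sig.id)
        return score_table(list(expr.columns), {sig.id: np.full(expr.shape[1], np.nan)})
    vals = expr.to_numpy(dtype=float)
    present = [g for g in genes if g in set(expr.index)]
    if len(present) < len(genes):
        log.warning(
            "signature %r: %d of %d genes absent from the matrix",
            sig.id,
            len(genes) - len(present),
            len(genes),
        )
    if sig.original_method == "mean":
        scores = vals[idx, :].mean(axis=0)
    else:
        coeffs = np.array([sig.coefficients[g] for g in present], dtype=float)
        scores = coeffs @ vals[idx, :]
    return score_table(list(expr.columns), {sig.id: scores})


# ---------------------------------------------------------------------------
# parallel dispatch
# ---------------------------------------------------------------------------

_ENGINES = {
    "zscore": score_zscore,
    "ssgsea": score_ssgsea,
    "singscore": score_singscore,
}


def parallel_score(
    expr: pd.DataFrame,
    sets: object,
    params: MethodParams | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Run an enrichment engine split across workers.

    Per-sample methods (ssGSEA, singscore) are partitioned by sample; the
    cohort-level combined z-score is computed whole (its z step couples all
    samples).  The result is bit-identical to ``n_workers=1`` because every
    per-sample computation is independent of the partition and cohort-level
    normalization is applied once to the reassembled table.
    """
    params = params or MethodParams(method="ssgsea")
    if n_workers < 1:
        raise InputError("n_workers must be >= 1")
    method = params.method
    if method == "original":
        raise InputError("parallel_score drives the generic engines; use score_original")
    engine = _ENGINES[method]
    n_samples = expr.shape[1]
    if n_workers == 1 or method == "zscore" or n_samples == 1:
        return engine(expr, sets, params) if method != "zscore" else engine(expr, sets)

    gene_sets = coerce_gene_sets(sets)
    chunks = [c for c in np.array_split(np.arange(n_samples), min(n_workers, n_samples)) if c.size]
    raw_params = params
    if method == "ssgsea" and params.ssgsea_norm != "raw":
        # compute raw per chunk; normalize once on the full table below
        raw_params = MethodParams(
            method="ssgsea",
            ssgsea_exponent=params.ssgsea_exponent,
            ssgsea_norm="raw",
            tie_rule=params.tie_rule,
        )
    parts = Parallel(n_jobs=n_workers)(
        delayed(engine)(expr.iloc[:, chunk], gene_sets, raw_params) for chunk in chunks
    )
    table = pd.concat(parts, axis=0, ignore_index=True)
    if method == "ssgsea" and params.ssgsea_norm != "raw":
        table = _normalize_ssgsea(table, params.ssgsea_norm)
    return table
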