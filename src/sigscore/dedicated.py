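"""Dedicated scorers: ESTIMATE-style, CINSARC-style, Immunophenoscore-style.

These three procedures get their own functions because a generic enrichment
engine does not reproduce them:

* **ESTIMATE** scores immune and stromal infiltration with raw ssGSEA
  (alpha = 0.25), sums them into the ESTIMATE score, and maps that sum to a
  tumor-purity estimate through a cosine calibration
  ``purity = cos(a + b * ESTIMATE)``.
* **CINSARC** is a nearest-centroid risk classifier: samples are assigned to
  the low-risk (C1) or high-risk (C2) group by Euclidean distance, in
  gene-standardized space, to leave-one-out class centroids built from a
  per-sample distant-metastasis label.
* **Immunophenoscore (IPS)** aggregates per-gene z-scores into immune marker
  scores, weighted category scores (MHC, EC, SC, CP), their sum ``az``, and a
  discrete 0-10 immunogenicity score.

All three return tidy DataFrames with one row per sample.  Default gene lists
and calibration constants are loaded from editable YAML files under
``sigscore/data`` (see each file's provenance notes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import SAMPLE_ID, GeneSet, InputError, MethodParams, score_table
from .methods import _present_indexer, score_ssgsea, zscore_matrix

log = logging.getLogger("sigscore")

__all__ = [
    "score_estimate",
    "classify_cinsarc",
    "score_immunophenoscore",
    "ips_from_az",
    "IpsConfig",
    "IpsMarker",
    "load_estimate_config",
    "load_cinsarc_genes",
    "load_ips_config",
]

IPS_CATEGORIES = ("MHC", "EC", "SC", "CP")


def _read_data_yaml(name: str) -> dict:
    with resources.files("sigscore.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# ESTIMATE
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def load_estimate_config() -> tuple[GeneSet, GeneSet, tuple[float, float]]:
    """Bundled immune/stromal gene sets and purity coefficients ``(a, b)``."""
    cfg = _read_data_yaml("estimate_demo_synthetic.yaml")
    immune = GeneSet("estimate_immune", tuple(cfg["immune_genes"]))
    stroma = GeneSet("estimate_stroma", tuple(cfg["stroma_genes"]))
    coeffs = (float(cfg["purity"]["a"]), float(cfg["purity"]["b"]))
    return immune, stroma, coeffs


def score_estimate(
    expr: pd.DataFrame,
    immune_set: GeneSet | None = None,
    stroma_set: GeneSet | None = None,
    purity_coeffs: tuple[float, float] | None | bool = True,
) -> pd.DataFrame:
    """Immune, stroma, ESTIMATE and tumor-purity scores per sample.

    Immune and stroma scores are raw ssGSEA enrichment scores (alpha = 0.25)
    of the two gene sets; the ESTIMATE score is their exact sum.  When purity
    coefficients ``(a, b)`` are available, ``purity = cos(a + b * ESTIMATE)``
    clamped to [0, 1]; samples whose cosine argument leaves the
    monotone-decreasing branch ``[0, pi]`` get NA with a warning.  Pass
    ``purity_coeffs=None`` to skip the purity column's calibration
    (defaults come from the bundled config).

    Raises ``InputError`` if either gene set has no gene in the matrix.
    """
    d_imm, d_str, d_coeffs = load_estimate_config()
    immune_set = immune_set or d_imm
    stroma_set = stroma_set or d_str
    coeffs = d_coeffs if purity_coeffs is True else purity_coeffs

    present = set(expr.index)
    for gs in (immune_set, stroma_set):
        if not (set(gs.genes) & present):
            raise InputError(f"gene set {gs.name!r} is entirely absent from the matrix")

    params = MethodParams(method="ssgsea", ssgsea_exponent=0.25, ssgsea_norm="raw")
    tbl = score_ssgsea(expr, {"immune_score": immune_set, "stroma_score": stroma_set}, params)
    immune = tbl["immune_score"].to_numpy()
    stroma = tbl["stroma_score"].to_numpy()
    estimate = immune + stroma

    purity = np.full(estimate.shape, np.nan)
    if coeffs is not None:
        a, b = float(coeffs[0]), float(coeffs[1])
        arg = a + b * estimate
        valid = (arg >= 0.0) & (arg <= math.pi)
        if not valid.all():
            log.warning(
                "%d sample(s) outside the valid purity branch [0, pi]; purity set to NA",
                int((~valid).sum()),
            )
        purity[valid] = np.clip(np.cos(arg[valid]), 0.0, 1.0)

    return score_table(
        list(expr.columns),
        {
            "immune_score": immune,
            "stroma_score": stroma,
            "estimate_score": estimate,
            "purity": purity,
        },
    )


# ---------------------------------------------------------------------------
# CINSARC
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def load_cinsarc_genes() -> GeneSet:
    cfg = _read_data_yaml("cinsarc_demo_synthetic.yaml")
    return GeneSet("cinsarc", tuple(cfg["genes"]))


def classify_cinsarc(
    expr: pd.DataFrame,
    dm_status: Mapping[str, int] | pd.Series,
    signature_genes: GeneSet | Sequence[str] | None = None,
    metric: str = "euclidean",
    restandardize: bool = False,
) -> pd.DataFrame:
    """Nearest-centroid CINSARC risk classification with leave-one-out centroids.

    ``dm_status`` maps every sample to 0 (no distant metastasis, low-risk
    reference) or 1 (metastasis).  Present signature genes are standardized
    across samples (mean 0, sd 1, divisor n-1); for each sample the per-gene
    centroids of the two label groups are recomputed with that sample held
    out, and the sample is called C1 when strictly closer to the
    no-metastasis centroid, C2 otherwise (ties are C2).

    ``metric`` may be ``euclidean`` (default) or ``correlation``
    (1 - Pearson).  ``restandardize=True`` re-standardizes genes within each
    leave-one-out fold instead of once on the full cohort.
    """
    if metric not in ("euclidean", "correlation"):
        raise InputError("metric must be 'euclidean' or 'correlation'")
    sig = signature_genes or load_cinsarc_genes()
    genes = sig.genes if isinstance(sig, GeneSet) else tuple(sig)

    samples = list(expr.columns)
    status = pd.Series(dm_status)
    missing = [s for s in samples if s not in status.index]
    if missing:
        raise InputError(f"dm_status missing label(s) for sample(s): {missing}")
    y = status.loc[samples].astype(int).to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise InputError("dm_status labels must be 0 (no metastasis) or 1")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise InputError(
                f"class {cls} has fewer than 2 samples; leave-one-out centroids undefined"
            )

    idx = _present_indexer(expr.index, genes)
    if idx.size == 0:
        raise InputError("no signature gene present in the expression matrix")
    X = expr.to_numpy(dtype=float)[idx, :].T  # samples x genes

    def _standardize(mat: np.ndarray) -> np.ndarray:
        mu = mat.mean(axis=0, keepdims=True)
        sd = mat.std(axis=0, ddof=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (mat - mu) / sd

    if not restandardize:
        Z = _standardize(X)

    def _dist(x: np.ndarray, c: np.ndarray) -> float:
        if metric == "euclidean":
            return float(np.linalg.norm(x - c))
        r = np.corrcoef(x, c)[0, 1]
        return float(1.0 - r)

    d0 = np.empty(len(samples))
    d1 = np.empty(len(samples))
    for i in range(len(samples)):
        if restandardize:
            mu = np.delete(X, i, axis=0).mean(axis=0)
            sd = np.delete(X, i, axis=0).std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
            Zi = (X - mu) / sd
        else:
            Zi = Z
        keep = np.ones(len(samples), dtype=bool)
        keep[i] = False
        g0 = keep & (y == 0)
        g1 = keep & (y == 1)
        if not g0.any() or not g1.any():
            raise InputError("a label class was emptied by leave-one-out")
        d0[i] = _dist(Zi[i], Zi[g0].mean(axis=0))
        d1[i] = _dist(Zi[i], Zi[g1].mean(axis=0))

    risk = np.where(d0 < d1, "C1", "C2")
    out = score_table(
        samples, {"distance_to_lowrisk": d0, "distance_to_highrisk": d1}
    )
    out["risk_class"] = risk
    return out


# ---------------------------------------------------------------------------
# Immunophenoscore
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IpsMarker:
    """One immune marker: a named gene list with a category and a weight."""

    name: str
    category: str
    genes: tuple[str, ...]
    weight: float

    def __post_init__(self) -> None:
        if self.category not in IPS_CATEGORIES:
            raise InputError(
                f"marker {self.name!r}: category must be one of {IPS_CATEGORIES}"
            )
        if not self.genes:
            raise InputError(f"marker {self.name!r}: gene list must be non-empty")


@dataclass(frozen=True)
class IpsConfig:
    """The marker/weight table driving the Immunophenoscore."""

    markers: tuple[IpsMarker, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise InputError("IpsConfig needs at least one marker")


@lru_cache(maxsize=1)
def load_ips_config() -> IpsConfig:
    cfg = _read_data_yaml("ips_demo_synthetic.yaml")
    markers = tuple(
        IpsMarker(
            name=m["name"],
            category=m["category"],
            genes=tuple(m["genes"]),
            weight=float(m["weight"]),
        )
        for m in cfg["markers"]
    )
    return IpsConfig(markers)


def ips_from_az(az: np.ndarray | float) -> np.ndarray:
    """Map the aggregated z-score ``az`` to the discrete 0-10 IPS.

    IPS is 0 for ``az <= 0`` and ``min(10, round(az * 10 / 3))`` otherwise,
    rounding half away from zero.
    """
    arr = np.atleast_1d(np.asarray(az, dtype=float))
    scaled = arr * 10.0 / 3.0
    rounded = np.floor(scaled + 0.5)  # half away from zero; scaled > 0 here
    ips = np.where(arr <= 0, 0.0, np.minimum(10.0, rounded))
    return ips.astype(int)


def score_immunophenoscore(
    expr: pd.DataFrame, config: IpsConfig | None = None
) -> pd.DataFrame:
    """Immune marker scores, category scores, ``az`` and the IPS per sample.

    Per-gene z-scores across samples feed marker scores (mean z over the
    marker's present genes); category scores are weight-normalized sums of
    their markers (``sum(w * s) / sum(|w|)``); ``az`` is the sum of the four
    category scores.  Markers with no gene present are dropped with a
    warning; a category losing all its markers is an error.
    """
    config = config or load_ips_config()
    z = zscore_matrix(expr).to_numpy()
    n_samples = expr.shape[1]

    marker_scores: dict[str, np.ndarray] = {}
    kept: list[IpsMarker] = []
    for m in config.markers:
        idx = _present_indexer(expr.index, m.genes)
        if idx.size == 0:
            log.warning("IPS marker %r: no genes present; marker dropped", m.name)
            continue
        marker_scores[m.name] = z[idx, :].mean(axis=0)
        kept.append(m)

    category_scores: dict[str, np.ndarray] = {}
    for cat in IPS_CATEGORIES:
        members = [m for m in kept if m.category == cat]
        if not members:
            raise InputError(f"no IPS marker of category {cat!r} has genes in the matrix")
        num = np.zeros(n_samples)
        den = 0.0
        for m in members:
            num += m.weight * marker_scores[m.name]
            den += abs(m.weight)
        category_scores[cat] = num / den

    az = sum(category_scores.values())
    cols: dict[str, np.ndarray] = {}
    cols.update(marker_scores)
    cols.update(category_scores)
    cols["az"] = az
    out = score_table(list(expr.columns), cols)
    out["ips"] = ips_from_az(az)
    return out
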