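"""Deterministic synthetic expression cohorts with known structure.

The generators emulate already-normalized, log-scale expression (i.i.d.
Gaussian around a baseline of 6 with unit standard deviation, the familiar
scale of log2 microarray intensities or log-CPM), with planted structure:

* :func:`make_cohort` up-shifts the genes of one gene set in a designated
  fraction of samples by ``effect_size`` standard deviations — the canonical
  setting in which every single-sample enrichment method should separate the
  spiked group;
* :func:`make_separable_classes` builds two Gaussian clusters ``delta``
  standard deviations apart per gene — the harness for the nearest-centroid
  classifier.

All randomness flows from one explicit seed; there is no global random
state, so equal seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneSet, InputError

__all__ = ["SpikeDesign", "make_cohort", "make_separable_classes"]

BASELINE_MEAN = 6.0
BASELINE_SD = 1.0


@dataclass(frozen=True)
class SpikeDesign:
    """Design of a spiked cohort.

    Defaults describe a mid-sized expression study: 1000 genes, 50 samples,
    a 25-gene signature up-shifted by 2 within-gene standard deviations in
    half the cohort.
    """

    n_genes: int = 1000
    n_samples: int = 50
    set_size: int = 25
    spiked_fraction: float = 0.5
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise InputError("need >=2 genes and >=2 samples")
        if not (0 < self.set_size < self.n_genes):
            raise InputError("set_size must satisfy 0 < set_size < n_genes")
        if not (0.0 < self.spiked_fraction < 1.0):
            raise InputError("spiked_fraction must lie strictly between 0 and 1")
        if not np.isfinite(self.effect_size):
            raise InputError("effect_size must be finite")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def make_cohort(design: SpikeDesign) -> tuple[pd.DataFrame, GeneSet, pd.Series]:
    """Generate a spiked cohort: (expression matrix, gene set, spike labels).

    Baseline expression is i.i.d. Normal(6, 1).  ``set_size`` randomly chosen
    genes form the returned set; in a randomly chosen ``spiked_fraction`` of
    samples their values are shifted up by ``effect_size``.  The boolean
    label series marks the spiked samples.
    """
    if not isinstance(design, SpikeDesign):
        design = SpikeDesign(**design)  # type: ignore[arg-type]
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)
    samples = _sample_ids(design.n_samples)
    values = rng.normal(BASELINE_MEAN, BASELINE_SD, size=(design.n_genes, design.n_samples))

    set_idx = rng.choice(design.n_genes, size=design.set_size, replace=False)
    n_spiked = max(1, round(design.spiked_fraction * design.n_samples))
    if n_spiked >= design.n_samples:
        n_spiked = design.n_samples - 1
    spiked_idx = rng.choice(design.n_samples, size=n_spiked, replace=False)
    values[np.ix_(set_idx, spiked_idx)] += design.effect_size

    expr = pd.DataFrame(values, index=genes, columns=samples)
    expr.index.name = "gene"
    gene_set = GeneSet("spiked_set", tuple(genes[i] for i in sorted(set_idx)))
    labels = pd.Series(False, index=samples, name="spiked")
    labels.iloc[sorted(spiked_idx)] = True
    return expr, gene_set, labels


def make_separable_classes(
    n_genes: int = 20,
    n_per_class: int = 15,
    delta: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two Gaussian clusters separated by ``delta`` sd per gene.

    Class 0 samples draw from Normal(6, 1) per gene, class 1 from
    Normal(6 + delta, 1).  Returns the expression matrix and an integer
    label series (0/1) over samples.
    """
    if n_per_class < 2:
        raise InputError("n_per_class must be >= 2")
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_class
    genes = _gene_ids(n_genes)
    samples = _sample_ids(n_samples)
    values = rng.normal(BASELINE_MEAN, BASELINE_SD, size=(n_genes, n_samples))
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    values[:, labels == 1] += delta
    expr = pd.DataFrame(values, index=genes, columns=samples)
    expr.index.name = "gene"
    return expr, pd.Series(labels, index=samples, name="dm_status")
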