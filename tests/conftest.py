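"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately use explicit loops over the statistic
definitions (running-sum walk for ssGSEA, mean-rank arithmetic for
singscore, literal leave-one-out centroid recomputation for CINSARC) so the
optimized engines are checked against an implementation that shares no code
path with them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_ssgsea(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Explicit running-sum walk over decreasing ranks (P_in/P_out arrays)."""
    values = np.asarray(values, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = values.size
    # competition-free ranks by counting (assumes no ties)
    ranks = np.array([1 + sum(1 for w in values if w < v) for v in values], dtype=float)
    order = sorted(range(n), key=lambda i: -ranks[i])
    k = int(in_set.sum())
    assert 0 < k < n
    denom = sum(ranks[i] ** alpha for i in order if in_set[i])
    p_in = np.empty(n)
    p_out = np.empty(n)
    cum_in, cum_out = 0.0, 0
    for pos, i in enumerate(order):
        if in_set[i]:
            cum_in += ranks[i] ** alpha
        else:
            cum_out += 1
        p_in[pos] = cum_in / denom
        p_out[pos] = cum_out / (n - k)
    return float((p_in - p_out).sum())


def brute_singscore_up(values: np.ndarray, up_idx: np.ndarray, center: bool) -> float:
    """Mean-rank formula evaluated by direct enumeration (assumes no ties)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = np.array([1 + sum(1 for w in values if w < v) for v in values], dtype=float)
    m = len(up_idx)
    mean_rank = float(np.mean([ranks[i] for i in up_idx]))
    r_min = (m + 1) / 2.0
    r_max = (2 * n - m + 1) / 2.0
    score = (mean_rank - r_min) / (r_max - r_min)
    return score - 0.5 if center else score


def brute_cinsarc(X: np.ndarray, y: np.ndarray) -> list[str]:
    """Literal LOOCV nearest-centroid labels on samples-x-genes data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    labels = []
    for i in range(X.shape[0]):
        c0 = np.mean([Z[j] for j in range(len(y)) if j != i and y[j] == 0], axis=0)
        c1 = np.mean([Z[j] for j in range(len(y)) if j != i and y[j] == 1], axis=0)
        d0 = np.sqrt(((Z[i] - c0) ** 2).sum())
        d1 = np.sqrt(((Z[i] - c1) ** 2).sum())
        labels.append("C1" if d0 < d1 else "C2")
    return labels


@pytest.fixture
def ssgsea_oracle():
    return brute_ssgsea


@pytest.fixture
def singscore_oracle():
    return brute_singscore_up


@pytest.fixture
def cinsarc_oracle():
    return brute_cinsarc


# ---------------------------------------------------------------------------
# small expression fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def toy_expr() -> pd.DataFrame:
    """3 genes x 2 samples, strictly ordered values, no ties."""
    return pd.DataFrame(
        {"sampA": [1.0, 2.0, 7.0], "sampB": [3.0, 6.0, 4.0]},
        index=["g1", "g2", "g3"],
    )


@pytest.fixture
def random_expr() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(60)]
    samples = [f"S{j:02d}" for j in range(8)]
    return pd.DataFrame(
        rng.normal(6, 1, size=(60, 8)), index=genes, columns=samples
    )
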