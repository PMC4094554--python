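"""Permutation-based FDR q-values for dependency scores, and the
hypergeometric test for the overlap of two gene sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import compute_lr, compute_mi
from .mic import MicParams, compute_mic

__all__ = [
    "PermutationNull",
    "OverlapTestResult",
    "build_null",
    "q_values",
    "hypergeom_overlap",
]


@dataclass
class PermutationNull:
    """Pooled permutation null for one dependency metric.

    ``scores`` holds the null sample sorted ascending.  The pooled scheme
    permutes the regulator vector once per permutation and scores it against
    one randomly chosen non-regulator gene; after rank-based grid
    construction the null is approximately exchangeable across genes, so a
    single pooled sample stands in for per-gene nulls at a fraction of the
    cost.
    """

    metric: str
    n_perm: int
    seed: int
    scores: np.ndarray = field(repr=False)


def _metric_fn(metric: str, mic_params: MicParams | None, n_bins: int | None):
    if metric == "mic":
        params = mic_params or MicParams()
        return lambda x, y: compute_mic(x, y, params)
    if metric == "mi":
        return lambda x, y: compute_mi(x, y, n_bins=n_bins)
    if metric == "lr":
        return lambda x, y: abs(compute_lr(x, y)["r"])
    raise ValueError(f"unknown metric {metric!r} (expected mic, mi or lr)")


def build_null(
    matrix: pd.DataFrame,
    regulator: str,
    metric: str = "mic",
    n_perm: int = 10_000,
    seed: int = 0,
    mic_params: MicParams | None = None,
    n_bins: int | None = None,
) -> PermutationNull:
    """Pooled permutation null: permute the regulator's expression vector and
    score it against a random non-regulator gene, n_perm times."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if regulator not in matrix.index:
        raise KeyError(f"regulator {regulator!r} not present in matrix")
    fn = _metric_fn(metric, mic_params, n_bins)
    rng = np.random.default_rng(seed)
    x = matrix.loc[regulator].to_numpy(dtype=np.float64)
    Y = matrix.loc[matrix.index != regulator].to_numpy(dtype=np.float64)
    null = np.empty(n_perm, dtype=np.float64)
    for i in range(n_perm):
        xp = rng.permutation(x)
        g = rng.integers(0, Y.shape[0])
        null[i] = fn(xp, Y[g])
    null.sort()
    return PermutationNull(metric=metric, n_perm=n_perm, seed=seed, scores=null)


def q_values(observed: pd.Series, null: PermutationNull) -> pd.Series:
    """Empirical-FDR q-value per gene from a pooled permutation null.

    For an observed score s with m scored genes and a null of size N,

        q(s) = [(#null >= s + 1) / (N + 1)] * m / max(1, #observed >= s)

    (the +1 pseudo-count avoids q = 0 at zero null exceedances), clipped to
    [0, 1] and then monotonised so q is non-increasing in the score.
    """
    if null.scores.size == 0:
        raise ValueError("null is empty")
    m = observed.size
    N = null.scores.size
    order = sorted(observed.index, key=lambda g: (-observed[g], g))
    s = observed.loc[order].to_numpy(dtype=np.float64)
    # null.scores ascending: exceedances of s
    exceed = N - np.searchsorted(null.scores, s, side="left")
    n_obs_ge = np.arange(1, m + 1)  # after descending sort, ties share a side
    # give tied observed scores the same (largest) count of observed >= s
    for i in range(m - 2, -1, -1):
        if s[i] == s[i + 1]:
            n_obs_ge[i] = n_obs_ge[i + 1]
    q_raw = ((exceed + 1) / (N + 1)) * m / np.maximum(1, n_obs_ge)
    q_raw = np.clip(q_raw, 0.0, 1.0)
    # suffix minimum: q(s) non-increasing in s
    q_mono = np.minimum.accumulate(q_raw[::-1])[::-1]
    return pd.Series(q_mono, index=pd.Index(order, name=observed.index.name)).reindex(
        observed.index
    )


@dataclass(frozen=True)
class OverlapTestResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets."""

    n_a: int
    n_b: int
    n_universe: int
    overlap: int
    p_value: float


def hypergeom_overlap(set_a, set_b, universe) -> OverlapTestResult:
    """P(overlap >= observed) when |A| and |B| genes are drawn without
    replacement from a universe of size N (R's ``phyper`` upper tail)."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise ValueError(f"set A has {len(a - u)} gene(s) outside the universe")
    if not b <= u:
        raise ValueError(f"set B has {len(b - u)} gene(s) outside the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapTestResult(
        n_a=len(a), n_b=len(b), n_universe=len(u), overlap=k, p_value=min(p, 1.0)
    )
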