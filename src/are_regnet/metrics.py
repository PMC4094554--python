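"""Pairwise dependency metrics: binned mutual information, ordinary least
squares, ARACNE-style DPI pruning, and regulator-vs-all scoring."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

from .mic import MicParams, _stable_ranks, _validate_pair, compute_mic

__all__ = [
    "DependencyResult",
    "compute_mi",
    "compute_lr",
    "dpi_prune",
    "score_regulator",
    "default_bins",
]


def default_bins(n: int) -> int:
    """Default equal-frequency bin count: ceil(n^(1/3))."""
    return max(2, int(math.ceil(n ** (1.0 / 3.0))))


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    # ties broken by stable sample-index order
    return _stable_ranks(v) * n_bins // v.size


def compute_mi(x, y, n_bins: int | None = None) -> float:
    """Plug-in mutual information (nats) on equal-frequency bins.

    MI(x, x) equals the entropy of the binned x, i.e. log(n_bins) when n is a
    multiple of n_bins.
    """
    x, y = _validate_pair(x, y, min_n=2)
    n = x.size
    if n_bins is None:
        n_bins = default_bins(n)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if n < n_bins:
        raise ValueError(f"need n >= n_bins, got n={n}, n_bins={n_bins}")
    bx = _equal_frequency_bins(x, n_bins)
    by = _equal_frequency_bins(y, n_bins)
    return float(mutual_info_score(bx, by))


def compute_lr(x, y) -> dict[str, float]:
    """Ordinary least-squares fit y = slope*x + intercept; r is the Pearson
    correlation, so sign(slope) == sign(r)."""
    x, y = _validate_pair(x, y, min_n=3)
    if np.ptp(x) == 0.0:
        raise ValueError("slope undefined: x is constant")
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept), "r": float(fit.rvalue)}


def dpi_prune(
    edges: list[tuple[str, str, float]], tolerance: float
) -> list[tuple[str, str, float]]:
    """ARACNE data-processing-inequality pruning of an MI-weighted edge list.

    For every triangle (a, b, c) the edge (a, c) is marked for removal when
    ``MI(a,c) < (1 - tolerance) * min(MI(a,b), MI(b,c))``.  All triangles are
    scanned against the original weights before anything is removed.
    ``tolerance=1.0`` (the published setting this package mirrors) disables
    pruning entirely; ``tolerance=0`` is the strict DPI.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError(f"tolerance must be in [0, 1], got {tolerance}")
    mi: dict[frozenset, float] = {}
    adj: dict[str, set[str]] = {}
    for a, b, w in edges:
        mi[frozenset((a, b))] = w
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    doomed: set[frozenset] = set()
    bound = 1.0 - tolerance
    for a, b, c in itertools.combinations(sorted(adj), 3):
        e_ab, e_bc, e_ac = frozenset((a, b)), frozenset((b, c)), frozenset((a, c))
        if e_ab not in mi or e_bc not in mi or e_ac not in mi:
            continue
        w_ab, w_bc, w_ac = mi[e_ab], mi[e_bc], mi[e_ac]
        if w_ac < bound * min(w_ab, w_bc):
            doomed.add(e_ac)
        if w_ab < bound * min(w_ac, w_bc):
            doomed.add(e_ab)
        if w_bc < bound * min(w_ab, w_ac):
            doomed.add(e_bc)
    return [(a, b, w) for a, b, w in edges if frozenset((a, b)) not in doomed]


@dataclass
class DependencyResult:
    """Per-gene dependency scores of one regulator against all other genes.

    ``scores`` is indexed by gene with columns mic, mi, lr_slope, lr_r and,
    once the significance module has run, q.
    """

    regulator: str
    scores: pd.DataFrame = field(repr=False)

    def ranked(self, metric: str = "mic") -> pd.Series:
        """Genes sorted by the given metric, descending, ties broken
        lexicographically on the gene identifier."""
        col = self.scores[metric]
        order = sorted(col.index, key=lambda g: (-col[g], g))
        return col.loc[order]


def score_regulator(
    matrix: pd.DataFrame,
    regulator: str,
    mic_params: MicParams | None = None,
    n_bins: int | None = None,
    metrics: tuple[str, ...] = ("mic", "mi", "lr"),
) -> DependencyResult:
    """Score every non-regulator gene of an expression matrix (genes x
    samples) against the regulator's expression vector."""
    if regulator not in matrix.index:
        raise KeyError(f"regulator {regulator!r} not present in matrix")
    if matrix.shape[1] < 3:
        raise ValueError("dependency scoring requires at least 3 samples")
    mic_params = mic_params or MicParams()
    x = matrix.loc[regulator].to_numpy(dtype=np.float64)
    others = matrix.index[matrix.index != regulator]
    Y = matrix.loc[others].to_numpy(dtype=np.float64)
    out = pd.DataFrame(index=others.copy())
    out.index.name = "gene"

    if "lr" in metrics:
        xc = x - x.mean()
        ssx = float(xc @ xc)
        if ssx == 0.0:
            raise ValueError("slope undefined: regulator expression is constant")
        Yc = Y - Y.mean(axis=1, keepdims=True)
        cov = Yc @ xc
        slopes = cov / ssx
        ssy = (Yc * Yc).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(ssy > 0.0, cov / np.sqrt(ssx * ssy), 0.0)
        out["lr_slope"] = slopes
        out["lr_r"] = r
    if "mi" in metrics:
        out["mi"] = [compute_mi(x, Y[i], n_bins=n_bins) for i in range(Y.shape[0])]
    if "mic" in metrics:
        out["mic"] = [compute_mic(x, Y[i], mic_params) for i in range(Y.shape[0])]
    cols = [c for c in ("mic", "mi", "lr_slope", "lr_r") if c in out.columns]
    return DependencyResult(regulator=regulator, scores=out[cols])
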