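"""Kolmogorov-Smirnov gene-set enrichment analysis of a ranked gene list.

A ranked list (genes sorted by a dependency score, descending) is walked from
top to bottom; meeting a gene-set member increments a running sum by that
gene's weight ``|score|**p`` (normalised over members), meeting a non-member
decrements it by ``1/(N - Nh)``.  The enrichment score (ES) is the signed
extremum of the running sum, which by construction returns to exactly 0 at
the end of the list.  With p=0 this is the classical two-sample KS statistic
on the member/non-member rank distributions.

Significance comes from gene-label permutation: null ES values are obtained
by drawing random sets of the same size from the list.  NES is the ES divided
by the mean |null ES| of matching sign; the FDR q is estimated from the
pooled null NES distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "nes_and_fdr",
    "validate_inference",
    "rank_genes",
]


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: tuple[str, ...] = field(repr=False)
    n_perm: int = 0
    seed: int = 0


def rank_genes(scores: pd.Series) -> pd.Series:
    """Sort a gene->score series descending, ties broken lexicographically on
    the gene identifier (deterministic ranked list)."""
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


def _members_of(geneset) -> tuple[str, set[str]]:
    # accepts an io.GeneSet or any iterable of gene identifiers
    name = getattr(geneset, "name", "gene_set")
    members = getattr(geneset, "genes", None)
    if members is None:
        members = geneset
    return name, set(members)


def _running_sum(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Running sum over the list; ``weights`` are |score|**p, ``mask`` marks
    set members."""
    n = mask.size
    nh = int(mask.sum())
    total = weights[mask].sum()
    steps = np.empty(n, dtype=np.float64)
    if total > 0.0:
        steps[mask] = weights[mask] / total
    else:  # all member weights zero (e.g. p>0 with zero scores): equal weights
        steps[mask] = 1.0 / nh
    steps[~mask] = -1.0 / (n - nh)
    return np.cumsum(steps)


def _es_of(running: np.ndarray) -> tuple[float, int]:
    hi = int(np.argmax(running))
    lo = int(np.argmin(running))
    # positive extremum wins exact ties in magnitude
    if running[hi] >= -running[lo]:
        return float(running[hi]), hi
    return float(running[lo]), lo


def enrichment_score(ranked: pd.Series, geneset, weight: float = 1.0):
    """ES of a gene set against a descending ranked list.

    Returns ``(es, running)`` where ``running`` is the full running-sum
    profile (length N, final value 0 up to float round-off).
    """
    if weight < 0:
        raise ValueError(f"weight must be >= 0, got {weight}")
    _, members = _members_of(geneset)
    genes = ranked.index
    mask = np.asarray(genes.isin(members))
    nh = int(mask.sum())
    if nh == 0:
        raise ValueError("gene set has no members in the ranked list")
    if nh == genes.size:
        raise ValueError("gene set covers the entire ranked list (miss step undefined)")
    weights = np.abs(ranked.to_numpy(dtype=np.float64)) ** weight
    running = _running_sum(weights, mask)
    es, _ = _es_of(running)
    return es, running


def _leading_edge(ranked: pd.Series, mask: np.ndarray, running: np.ndarray) -> tuple[str, ...]:
    es, peak = _es_of(running)
    genes = ranked.index.to_numpy()
    if es >= 0:
        sel = mask & (np.arange(mask.size) <= peak)
    else:
        sel = mask & (np.arange(mask.size) >= peak)
    return tuple(genes[sel])


def nes_and_fdr(
    ranked: pd.Series,
    genesets,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """ES, NES, nominal p and FDR q for each gene set against one ranked list.

    Null ES values come from random same-size draws of gene labels from the
    list.  The q estimate is conservative: the pooled null NES sample (both
    signs) forms the numerator tail fraction with a +1 pseudo-count.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    genes = ranked.index
    n = genes.size
    weights = np.abs(ranked.to_numpy(dtype=np.float64)) ** weight

    per_set = []
    null_nes_pool: list[np.ndarray] = []
    for gs in genesets:
        name, members = _members_of(gs)
        mask = np.asarray(genes.isin(members))
        nh = int(mask.sum())
        if nh == 0:
            raise ValueError(f"gene set {name!r} has no members in the ranked list")
        if nh == n:
            raise ValueError(f"gene set {name!r} covers the entire ranked list")
        running = _running_sum(weights, mask)
        es, _ = _es_of(running)
        le = _leading_edge(ranked, mask, running)

        null_es = np.empty(n_perm, dtype=np.float64)
        for i in range(n_perm):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=nh, replace=False)] = True
            null_es[i] = _es_of(_running_sum(weights, m))[0]
        pos = null_es[null_es > 0]
        neg = null_es[null_es < 0]
        mean_pos = pos.mean() if pos.size else np.abs(null_es).mean() or 1.0
        mean_neg = np.abs(neg).mean() if neg.size else np.abs(null_es).mean() or 1.0
        nes = es / mean_pos if es >= 0 else es / mean_neg
        null_nes = np.where(null_es >= 0, null_es / mean_pos, null_es / mean_neg)
        null_nes_pool.append(null_nes)

        same = pos if es >= 0 else neg
        if same.size:
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + same.size)
        else:  # degenerate null entirely of the opposite sign
            p = 1.0 / (1 + n_perm)
        per_set.append((name, es, float(nes), float(p), le, mask))

    pool = np.concatenate(null_nes_pool)
    obs_nes = np.array([r[2] for r in per_set])
    results = []
    for name, es, nes, p, le, _mask in per_set:
        if nes >= 0:
            num = (1 + int((pool >= nes).sum())) / (1 + pool.size)
            den = int((obs_nes >= nes).sum()) / obs_nes.size
        else:
            num = (1 + int((pool <= nes).sum())) / (1 + pool.size)
            den = int((obs_nes <= nes).sum()) / obs_nes.size
        q = min(1.0, num / den)
        results.append(
            EnrichmentResult(
                gene_set=name,
                es=es,
                nes=nes,
                p_value=p,
                fdr_q=q,
                leading_edge=le,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def validate_inference(
    scores: dict[str, pd.Series],
    genesets,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA of each validation gene set against the ranking induced by each
    dependency metric; returns a tidy (metric, gene_set) table of ES/NES/p/q."""
    universes = {m: frozenset(s.index) for m, s in scores.items()}
    first = next(iter(universes.values()))
    for m, u in universes.items():
        if u != first:
            raise ValueError(f"metric {m!r} is scored on a different gene universe")
    for gs in genesets:
        name, members = _members_of(gs)
        if not members & set(first):
            raise ValueError(f"validation set {name!r} is disjoint from the gene universe")
    rows = []
    for metric, s in scores.items():
        ranked = rank_genes(s)
        for res in nes_and_fdr(ranked, genesets, weight=weight, n_perm=n_perm, seed=seed):
            rows.append(
                {
                    "metric": metric,
                    "gene_set": res.gene_set,
                    "es": res.es,
                    "nes": res.nes,
                    "p_value": res.p_value,
                    "fdr_q": res.fdr_q,
                }
            )
    return pd.DataFrame(rows)
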