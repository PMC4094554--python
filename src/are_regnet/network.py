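"""Target filtering and regulator->target network assembly.

The final target list of a regulator is the intersection of four filters on
its dependency scores: permutation-FDR q-value, >= min ARE motif copies in
the 3'UTR, negative LR slope (expression inversely correlated with the
regulator, the signature of targeted degradation), and membership in a
configured annotation-term set (e.g. apoptosis/programmed-cell-death terms).
Each surviving gene carries a per-filter provenance record.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .metrics import DependencyResult
from .significance import OverlapTestResult, hypergeom_overlap

__all__ = [
    "TargetFilterConfig",
    "filter_targets",
    "selected_targets",
    "build_network",
    "pairwise_overlap_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetFilterConfig:
    q_threshold: float = 0.01
    min_are_copies: int = 2
    require_negative_lr: bool = True
    annotation_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError(f"q_threshold must be in (0, 1), got {self.q_threshold}")
        if self.min_are_copies < 1:
            raise ValueError("min_are_copies must be >= 1")


def _copy_counts(hitsets) -> dict[str, int]:
    return {
        g: (hs if isinstance(hs, int) else hs.copy_count) for g, hs in hitsets.items()
    }


def filter_targets(
    dep: DependencyResult,
    hitsets,
    annotation: dict[str, set] | None,
    cfg: TargetFilterConfig,
) -> pd.DataFrame:
    """Apply the filter cascade to one regulator's scored genes.

    ``dep.scores`` must carry a ``q`` column (from the significance module).
    ``hitsets`` maps gene -> MotifHitSet (or plain copy count); genes absent
    from it fail the ARE filter (logged).  An empty ``annotation_terms``
    config skips the annotation filter.  Returns a provenance table (one row
    per scored gene, boolean column per filter, ``selected`` for the
    intersection), ordered by MIC score descending among selected genes
    first.
    """
    scores = dep.scores
    if "q" not in scores.columns:
        raise ValueError("dependency scores carry no q column; run the significance stage")
    copies = _copy_counts(hitsets)
    missing_utr = [g for g in scores.index if g not in copies]
    if missing_utr:
        logger.info(
            "%d gene(s) have no 3'UTR sequence and fail the ARE filter", len(missing_utr)
        )
    out = pd.DataFrame(index=scores.index.copy())
    out["mic"] = scores.get("mic")
    out["q"] = scores["q"]
    out["lr_slope"] = scores.get("lr_slope")
    out["are_copies"] = [copies.get(g, 0) for g in scores.index]
    out["pass_q"] = scores["q"] <= cfg.q_threshold
    out["pass_are"] = out["are_copies"] >= cfg.min_are_copies
    if cfg.require_negative_lr:
        out["pass_lr"] = scores["lr_slope"] < 0
    else:
        out["pass_lr"] = True
    if cfg.annotation_terms:
        ann = annotation or {}
        out["pass_annotation"] = [
            bool(ann.get(g, set()) & cfg.annotation_terms) for g in scores.index
        ]
    else:
        out["pass_annotation"] = True
    out["selected"] = (
        out["pass_q"] & out["pass_are"] & out["pass_lr"] & out["pass_annotation"]
    )
    out = out.sort_values(["selected", "mic"], ascending=[False, False], kind="stable")
    out.index.name = "gene"
    return out


def selected_targets(provenance: pd.DataFrame) -> list[str]:
    """Genes passing every enabled filter, ordered by MIC descending."""
    return provenance.index[provenance["selected"]].tolist()


def build_network(targets_per_regulator: dict[str, pd.DataFrame]) -> nx.DiGraph:
    """Union regulator->target graph over regulators.

    Values may be ``filter_targets`` provenance tables (only selected rows
    are used) or plain iterables of target genes.  Edges carry mic, q and
    lr_sign attributes when available; node/edge insertion order is sorted
    and deterministic.  Self-edges are never created.
    """
    g = nx.DiGraph()
    for regulator in sorted(targets_per_regulator):
        g.add_node(regulator, kind="regulator")
        entry = targets_per_regulator[regulator]
        if isinstance(entry, pd.DataFrame):
            rows = entry.loc[entry["selected"]]
            for gene in sorted(rows.index):
                if gene == regulator:
                    continue
                row = rows.loc[gene]
                slope = row.get("lr_slope")
                g.add_edge(
                    regulator,
                    gene,
                    mic=float(row["mic"]) if pd.notna(row.get("mic")) else None,
                    q=float(row["q"]),
                    lr_sign=(0 if pd.isna(slope) else (1 if slope > 0 else -1)),
                )
        else:
            for gene in sorted(entry):
                if gene != regulator:
                    g.add_edge(regulator, gene)
    return g


def pairwise_overlap_report(
    targets_per_regulator: dict[str, set], universe
) -> dict[tuple[str, str], OverlapTestResult]:
    """Hypergeometric overlap test for every unordered regulator pair."""
    if len(targets_per_regulator) < 2:
        raise ValueError("need at least two regulators for a pairwise report")
    report = {}
    for a, b in itertools.combinations(sorted(targets_per_regulator), 2):
        report[(a, b)] = hypergeom_overlap(
            set(targets_per_regulator[a]), set(targets_per_regulator[b]), universe
        )
    return report
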