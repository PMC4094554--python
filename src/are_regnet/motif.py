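"""AU-rich element (ARE) motif scanning of 3'UTR sequences.

The default pattern is the 13-bp ARE consensus WWWU(AUUUA)UUUW bound by
ZFP36-family proteins, written in IUPAC code with W = A or U.  Scanning is
strand-as-given (3'UTRs are sense strand), T and U are interchangeable on
both the sequence and pattern side, matching is case-insensitive, and N (or
any other ambiguity code) in the sequence never matches.  Coordinates are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MotifPattern", "MotifHitSet", "scan_sequence", "scan_fasta", "are_filter"]

ARE_CONSENSUS = "WWWUAUUUAUUUW"

# IUPAC nucleotide codes expanded over the DNA alphabet (U is normalised to T)
_IUPAC: dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQUENCE_ALPHABET = frozenset("ACGTUN")


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC motif pattern; default is the 13-bp ARE consensus."""

    iupac: str = ARE_CONSENSUS

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("motif pattern must be non-empty")
        bad = [c for c in self.iupac.upper() if c not in _IUPAC]
        if bad:
            raise ValueError(f"non-IUPAC code(s) in pattern: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def allowed(self) -> tuple[frozenset, ...]:
        return tuple(_IUPAC[c] for c in self.iupac.upper())


@dataclass
class MotifHitSet:
    """Motif occurrences in one sequence; ``hits`` are (1-based start,
    matched subsequence) sorted by start."""

    gene: str
    hits: list[tuple[int, str]] = field(default_factory=list)

    @property
    def copy_count(self) -> int:
        return len(self.hits)


def _normalise(seq: str) -> str:
    s = seq.upper()
    for pos, ch in enumerate(s, start=1):
        if ch not in _SEQUENCE_ALPHABET:
            raise ValueError(f"illegal character {ch!r} at position {pos}")
    return s.replace("U", "T")


def scan_sequence(
    seq: str,
    pattern: MotifPattern | str = ARE_CONSENSUS,
    gene: str = "",
    allow_overlap: bool = True,
) -> MotifHitSet:
    """All windows of ``seq`` matching the pattern (step 1; overlapping
    windows counted separately unless ``allow_overlap`` is False, in which
    case counting is greedy left-to-right)."""
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    allowed = pattern.allowed
    k = len(allowed)
    s = _normalise(seq)
    hits: list[tuple[int, str]] = []
    i = 0
    while i <= len(s) - k:
        ok = True
        for j in range(k):
            # ambiguity codes in the sequence (N) are not in any allowed set
            if s[i + j] not in allowed[j]:
                ok = False
                break
        if ok:
            hits.append((i + 1, seq[i : i + k]))
            i += k if not allow_overlap else 1
        else:
            i += 1
    return MotifHitSet(gene=gene, hits=hits)


def scan_fasta(
    sequences: dict[str, str],
    pattern: MotifPattern | str = ARE_CONSENSUS,
    allow_overlap: bool = True,
) -> dict[str, MotifHitSet]:
    """Scan a gene->sequence mapping; returns a gene->MotifHitSet mapping."""
    return {
        gene: scan_sequence(seq, pattern, gene=gene, allow_overlap=allow_overlap)
        for gene, seq in sequences.items()
    }


def are_filter(hitsets: dict[str, MotifHitSet], min_copies: int = 2) -> set[str]:
    """Genes whose 3'UTR carries at least ``min_copies`` motif copies."""
    if min_copies < 1:
        raise ValueError(f"min_copies must be >= 1, got {min_copies}")
    return {g for g, hs in hitsets.items() if hs.copy_count >= min_copies}
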