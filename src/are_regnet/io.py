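"""Readers and writers for the pipeline's external formats.

TSV (expression matrix, annotations, score/hit tables), FASTA (3'UTRs), GMT
(gene sets), RNK (ranked lists) and SIF (Cytoscape simple interaction
format).  Readers validate strictly and reject malformed input rather than
coercing it; writers are deterministic, and every write->read round trip is
the identity.  All coordinates in reports are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSet",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_rnk",
    "write_rnk",
    "read_sif",
    "write_sif",
    "read_annotations_tsv",
    "write_annotations_tsv",
]

SIF_INTERACTION = "degrades"


@dataclass(frozen=True)
class GeneSet:
    """Named gene set (GMT record); members are unique, case-preserved."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


# -- expression matrices ----------------------------------------------------


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x sample expression matrix: header row of sample identifiers,
    first column gene identifiers, numeric cells, no missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifier(s): {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifier(s): {dupes}")
    try:
        values = df.astype(np.float64)
    except ValueError as exc:
        for gene, row in df.iterrows():
            bad = row[pd.to_numeric(row, errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value {bad.iloc[0]!r} in row {gene!r}"
                ) from exc
        raise
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise ValueError(f"missing value in row {gene!r}")
    values.index.name = "gene"
    return values


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# -- GMT gene sets ----------------------------------------------------------


def read_gmt(path) -> list[GeneSet]:
    """GMT: one gene set per line, tab-separated name, description, members.
    Duplicate members are collapsed with a warning."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT record needs >= 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"line {lineno}: gene set {name!r} has duplicate members; collapsed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, description=description, genes=tuple(unique)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join((gs.name, gs.description, *gs.genes)) + "\n")


# -- FASTA ------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an id->sequence mapping, sequences uppercased."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError("FASTA record with empty identifier")
        if rec.id in records:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records[rec.id] = seq
    return records


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# -- RNK ranked lists -------------------------------------------------------


def write_rnk(ranked: pd.Series, path) -> None:
    """Two-column gene/score file, already in ranked (descending) order."""
    ranked.to_csv(path, sep="\t", header=False, float_format="%.10g")


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"], dtype={0: str})
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene(s) in RNK file: {dupes}")
    s = pd.Series(df["score"].to_numpy(np.float64), index=pd.Index(df["gene"], name="gene"))
    return s


# -- SIF networks -----------------------------------------------------------


def write_sif(network, path, interaction: str = SIF_INTERACTION) -> None:
    """Cytoscape SIF: one ``regulator <interaction> target`` line per edge,
    sorted for determinism; isolated nodes written as single-field lines."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for node in sorted(n for n in network.nodes() if network.degree(n) == 0):
            fh.write(f"{node}\n")


def read_sif(path):
    """Re-import a SIF file as a directed graph (edge attributes are not
    stored in SIF)."""
    import networkx as nx

    g = nx.DiGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and fields[0]:
                g.add_node(fields[0])
            elif len(fields) >= 3:
                src, interaction, *targets = fields
                for t in targets:
                    g.add_edge(src, t, interaction=interaction)
            elif any(fields):
                raise ValueError(f"line {lineno}: malformed SIF record")
    return g


# -- annotation tables ------------------------------------------------------


def read_annotations_tsv(path) -> dict[str, set[str]]:
    """Gene -> annotation-term mapping; one (gene, term[, label]) row per
    line, tab-separated, with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation table needs at least gene and term columns")
    gene_col, term_col = df.columns[0], df.columns[1]
    if df[term_col].isna().any() or (df[term_col].str.len() == 0).any():
        raise ValueError("annotation table has empty term identifiers")
    ann: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        ann.setdefault(gene, set()).add(term)
    return ann


def write_annotations_tsv(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
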