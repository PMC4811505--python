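"""Readers and writers for the pipeline's file formats.

Plain-text formats throughout: FASTA for sequences (via Biopython), TSV with
header rows for counts, designs, expression and results, GMT for pathway
gene sets, and a three-column edge list (nodeA, nodeB, confidence) for the
interaction network. Every writer/reader pair round-trips losslessly; parse
errors report line numbers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import CountMatrix, validate_design
from .simulate import GeneSet


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA records as (id, uppercase sequence) pairs."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated FASTA ids in {path}: {dup}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample counts; first column gene ids, nonnegative integers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty counts table {path}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated gene id {dup!r} in {path}")
    neg = (df.values < 0)
    if neg.any():
        import numpy as np

        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"negative count in {path} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    return validate_design(design)


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_count_matrix(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    return CountMatrix(counts=read_counts_tsv(counts_path), design=read_design_tsv(design_path))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then member genes."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            sets.append(GeneSet(name=parts[0], genes=frozenset(parts[2:])))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Edge list TSV with header nodeA, nodeB, confidence."""
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty edge list {path}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                conf = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad confidence {parts[2]!r}") from None
            edges.append((parts[0], parts[1], conf))
    return edges


def write_edge_list(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("nodeA\tnodeB\tconfidence\n")
        for u, v, conf in edges:
            fh.write(f"{u}\t{v}\t{conf:g}\n")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneSet(name=name or Path(path).stem, genes=frozenset(genes))


def write_gene_set(genes, path: str | Path) -> None:
    members = sorted(getattr(genes, "genes", genes))
    with open(path, "w") as fh:
        fh.writelines(g + "\n" for g in members)


def write_results_tsv(table: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    table.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Knockdown/control expression: gene, kd_1..n, ctrl_1..n."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    kd = [c for c in df.columns if c.startswith("kd_")]
    ctrl = [c for c in df.columns if c.startswith("ctrl_")]
    if not kd or len(kd) != len(ctrl):
        raise ValueError(f"{path}: expected matched kd_*/ctrl_* columns, got {list(df.columns)}")
    return df
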