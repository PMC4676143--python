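"""Shared domain types and file I/O for the SP/SPH annotation pipeline.

Protein sequences travel as FASTA, gene models as GFF3 (1-based inclusive
coordinates throughout, as in the format itself), expression matrices as
genes x samples TSV with an explicit missing-value sentinel, and qPCR data
as long-format TSV (gene, sample, replicate, Ct).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "AA_ALPHABET",
    "ProteinRecord",
    "GeneModel",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_expression",
    "write_expression",
    "read_qpcr",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One family member: a predicted protein, optionally linked to its gene model.

    Sequences are amino acids over the 20 standard letters plus the
    ambiguity code X; X never matches a motif position downstream.
    """

    id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains non-amino-acid "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene on a scaffold with its CDS exons in transcription order.

    Coordinates are 1-based inclusive.  For minus-strand genes the exon
    list runs highest-coordinate first, i.e. 5'->3' on the transcript.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no CDS exons")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
        for s, e in self.exons:
            if s < self.start or e > self.end or s > e:
                raise ValueError(
                    f"gene {self.gene_id!r}: exon ({s},{e}) outside gene span"
                )
        if self.cds_length < 3:
            raise ValueError(f"gene {self.gene_id!r}: total CDS length < 3")

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)


class ExpressionMatrix:
    """Genes x samples RPKM matrix with explicit missing-value semantics.

    Internally a float DataFrame; NaN marks *missing* (not measured),
    which is distinct from 0.0 (measured, silent).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample labels in expression matrix")
        values = data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("negative RPKM value in expression matrix")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.genes)} genes x "
            f"{len(self.samples)} samples, {self.n_missing()} missing)"
        )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into records.

    Sequences are uppercased; a single trailing stop codon ``*`` is
    stripped.  Duplicate ids and empty sequences are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + CDS features, CDS linked via Parent) from GFF3.

    Exons are returned in transcription order: ascending coordinates on
    '+', descending on '-'.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            raise ValueError(f"gene {gene.id!r} has no CDS features")
        scaffolds = {c.seqid for c in cds} | {gene.seqid}
        if len(scaffolds) > 1:
            raise ValueError(
                f"gene {gene.id!r} has CDS on multiple scaffolds: {sorted(scaffolds)}"
            )
        exons = [(c.start, c.end) for c in cds]
        if gene.strand == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                scaffold=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(exons),
            )
        )
    # CDS lines whose Parent is not a gene in the file
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        if not parents or not any(p in gene_ids for p in parents):
            raise ValueError(f"CDS at {c.seqid}:{c.start}-{c.end} has no parent gene")
    return models


def write_gff(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.scaffold, g.start, g.gene_id)):
            fh.write(
                f"{m.scaffold}\tspfam\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.scaffold}\tspfam\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={m.gene_id}.cds;Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Expression TSV

def read_expression(
    path: str | Path, missing_sentinel: str = "NA"
) -> ExpressionMatrix:
    """Read a genes x samples RPKM TSV (first column = gene id).

    Empty cells and the sentinel (default "NA") become missing.  Zeros are
    data, not missing.  Ragged rows and negative values are hard errors.
    """
    with open(path) as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"empty expression file {path}")
    header = rows[0]
    ncol = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(f"{path}: ragged row at line {i}")
    text = "\n".join("\t".join(r) for r in rows)
    df = pd.read_csv(
        io.StringIO(text),
        sep="\t",
        index_col=0,
        na_values=[missing_sentinel, ""],
        keep_default_na=False,
    )
    return ExpressionMatrix(df)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, missing_sentinel: str = "NA"
) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep=missing_sentinel)


# ---------------------------------------------------------------------------
# qPCR table

def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR table: columns gene, sample, replicate, Ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "replicate", "Ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    if (df["Ct"] <= 0).any():
        raise ValueError("qPCR Ct values must be positive")
    return df
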