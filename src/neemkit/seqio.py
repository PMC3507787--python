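"""Sequence, gene-model and table I/O, plus assembly length statistics.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary.  Sequences are uppercased on read; soft-masking is
discarded.  FASTQ qualities are checked for format validity but not stored.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from ._seq import VALID_BASES

_INVALID_CHAR = re.compile(r"[^ACGTN]")


class SequenceParseError(ValueError):
    """A record failed format or alphabet validation."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        bad = _INVALID_CHAR.search(self.seq)
        if bad:
            raise SequenceParseError(
                f"record {self.id!r}: invalid character {bad.group()!r} "
                f"at position {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssemblyStats:
    """Length statistics of an assembly (Nx = length of the sequence at which
    the descending cumulative length first reaches x% of the total)."""

    n_sequences: int
    total_length: int
    longest: int
    n50: int
    n90: int

    def __post_init__(self):
        assert self.n50 >= self.n90 >= 0
        assert self.longest >= self.n50
        assert self.total_length >= self.longest


def read_sequences(path, format: str = "fasta", invalid: str = "raise") -> list[SequenceRecord]:
    """Read FASTA or FASTQ into SequenceRecords (order preserved, uppercased).

    ``invalid`` controls characters outside {A,C,G,T,N}: ``"raise"`` (default)
    rejects the record, ``"mask"`` maps them to N.  FASTQ qualities are parsed
    (format validation) and discarded.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    if invalid not in ("raise", "mask"):
        raise ValueError(f"invalid= must be 'raise' or 'mask', got {invalid!r}")
    out: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(os.fspath(path), format):
            seq = str(rec.seq).upper()
            if invalid == "mask":
                seq = _INVALID_CHAR.sub("N", seq)
            try:
                out.append(SequenceRecord(rec.id, seq, rec.description))
            except SequenceParseError as e:
                raise SequenceParseError(f"{path}: {e}") from e
    except ValueError as e:
        if isinstance(e, SequenceParseError):
            raise
        raise SequenceParseError(f"{path}: malformed {format}: {e}") from e
    return out


def write_sequences(records, path, format: str = "fasta", width: int = 60) -> None:
    """Write records as FASTA (wrapped at ``width``) or FASTQ (constant quality I).

    Output is byte-identical for identical inputs; ``read_sequences`` of the
    result reproduces ids, sequences and order.
    """
    records = list(records)
    with open(path, "w") as fh:
        if format == "fasta":
            for r in records:
                header = f">{r.id} {r.description}".rstrip() if r.description else f">{r.id}"
                fh.write(header + "\n")
                for i in range(0, max(len(r.seq), 1), width):
                    chunk = r.seq[i : i + width]
                    if chunk or len(r.seq) == 0:
                        fh.write(chunk + "\n")
                    if len(r.seq) == 0:
                        break
        elif format == "fastq":
            for r in records:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
        else:
            raise ValueError(f"unsupported format {format!r}")


def assembly_stats(records) -> AssemblyStats:
    """N50/N90 and companions from a collection of records (or raw lengths)."""
    lengths = sorted(
        (len(r) if not isinstance(r, int) else r) for r in records
    )
    if not lengths:
        raise ValueError("assembly_stats requires at least one sequence")
    if lengths[0] <= 0:
        raise ValueError("assembly_stats requires positive-length sequences")
    lengths.reverse()
    total = sum(lengths)
    cum = np.cumsum(lengths)
    n50 = lengths[int(np.searchsorted(cum, 0.5 * total))]
    n90 = lengths[int(np.searchsorted(cum, 0.9 * total))]
    return AssemblyStats(
        n_sequences=len(lengths),
        total_length=total,
        longest=lengths[0],
        n50=n50,
        n90=n90,
    )


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gene_models(path):
    """Parse gene/mRNA/exon GFF3 into GeneModels (one per mRNA, or per gene
    when no mRNA level exists).  GFF3 1-based inclusive coordinates become
    0-based half-open; exons are stored sorted by genomic start."""
    import gffutils

    from .gene_structure import GeneModel

    db = gffutils.create_db(
        os.fspath(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    exon_parents: dict[str, list[tuple[int, int, str, str]]] = {}
    known_ids = {f.id for f in db.all_features()}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent")
        if not parents:
            raise SequenceParseError(f"{path}: exon at {exon.seqid}:{exon.start} has no Parent")
        for p in parents:
            if p not in known_ids:
                raise SequenceParseError(f"{path}: exon Parent {p!r} is not a known feature")
            exon_parents.setdefault(p, []).append(
                (exon.start - 1, exon.end, exon.strand, exon.seqid)
            )
    carriers = list(db.features_of_type("mRNA"))
    if not carriers:
        carriers = list(db.features_of_type("gene"))
    for feat in carriers:
        raw = exon_parents.get(feat.id)
        if not raw:
            continue
        raw.sort()
        exons = tuple((s, e) for s, e, _, _ in raw)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise SequenceParseError(
                    f"{path}: overlapping exons in {feat.id}: [{s1},{e1}) and [{s2},{e2})"
                )
        models.append(
            GeneModel(
                gene_id=feat.id,
                scaffold=feat.seqid,
                strand=feat.strand if feat.strand in "+-" else "+",
                exons=exons,
            )
        )
    return models


def write_gene_models(models, path) -> None:
    """Emit gene/mRNA/exon GFF3 (1-based inclusive) for a set of GeneModels."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.exons[0][0] + 1, m.exons[-1][1]
            fh.write(
                f"{m.scaffold}\tneemkit\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            mrna = f"{m.gene_id}.mRNA"
            fh.write(
                f"{m.scaffold}\tneemkit\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.scaffold}\tneemkit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Tables

def read_table(path, kind: str):
    """Read a header-bearing TSV of the given kind.

    ``expression``: first column gene id, remaining columns numeric FPKM per
    organ/species -> ExpressionTable.  ``ortholog_map``: two columns
    (ref_id, other_id) -> DataFrame.  ``ltr_pairs``: columns element_id,
    five_prime, three_prime -> list of LTRPair.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if kind == "expression":
        from .expression import ExpressionTable

        ids = df.iloc[:, 0]
        dup = ids[ids.duplicated()]
        if not dup.empty:
            raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
        values = df.iloc[:, 1:]
        num = values.apply(pd.to_numeric, errors="coerce")
        if num.isna().any().any():
            r, c = next(zip(*np.where(num.isna().values)))
            raise ValueError(
                f"{path}: non-numeric or missing FPKM at row {ids.iloc[r]!r}, "
                f"column {values.columns[c]!r}"
            )
        num.index = pd.Index(ids, name=df.columns[0])
        return ExpressionTable(num)
    if kind == "ortholog_map":
        if df.shape[1] < 2:
            raise ValueError(f"{path}: ortholog map needs two columns")
        out = df.iloc[:, :2].copy()
        out.columns = ["ref_id", "other_id"]
        return out
    if kind == "ltr_pairs":
        from .ltr_dating import LTRPair

        needed = {"element_id", "five_prime", "three_prime"}
        if not needed.issubset(df.columns):
            raise ValueError(f"{path}: ltr_pairs table needs columns {sorted(needed)}")
        return [
            LTRPair(
                element_id=row.element_id,
                five_prime=SequenceRecord(f"{row.element_id}_5p", row.five_prime),
                three_prime=SequenceRecord(f"{row.element_id}_3p", row.three_prime),
            )
            for row in df.itertuples()
        ]
    raise ValueError(f"unknown table kind {kind!r}")
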