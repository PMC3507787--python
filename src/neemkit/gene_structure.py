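"""Gene-structure statistics: intron derivation, summary tables, first
exon/intron extraction, and the structure-vs-expression comparison.

A GeneModel is a stranded, ordered set of non-overlapping exon intervals
(0-based half-open, genomic order) on one scaffold; introns are the gaps
between consecutive exons.  Summary statistics follow the draft-genome
reporting convention: per-element means with sample SD (ddof = 1), and
exonic/intronic GC computed per gene over the concatenated exonic (resp.
intronic) sequence then averaged across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import per_record_gc
from .seqio import SequenceRecord

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in "+-" or len(self.strand) != 1:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if e - s < 1:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) has length < 1")
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons overlap or touch at {prev_end}/{s} "
                    "(zero-length introns are not representable)"
                )
            prev_end = e
        object.__setattr__(self, "exons", tuple(tuple(x) for x in self.exons))

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def derive_introns(model: GeneModel) -> list[Interval]:
    """Introns are the gaps between consecutive exons, in genomic order."""
    return [
        (a[1], b[0]) for a, b in zip(model.exons, model.exons[1:])
    ]


@dataclass(frozen=True)
class StructureSummary:
    """Table-1c-style per-element means and sample SDs."""

    n_genes: int
    gene_length_mean: float
    gene_length_sd: float
    exon_length_mean: float
    exon_length_sd: float
    intron_length_mean: float
    intron_length_sd: float
    exons_per_gene_mean: float
    exons_per_gene_sd: float
    introns_per_gene_mean: float
    introns_per_gene_sd: float
    exonic_gc_mean: float
    exonic_gc_sd: float
    intronic_gc_mean: float
    intronic_gc_sd: float

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("Number of genes", self.n_genes, np.nan),
            ("Gene length", self.gene_length_mean, self.gene_length_sd),
            ("Exon length", self.exon_length_mean, self.exon_length_sd),
            ("Intron length", self.intron_length_mean, self.intron_length_sd),
            ("Number of exons", self.exons_per_gene_mean, self.exons_per_gene_sd),
            ("Number of introns", self.introns_per_gene_mean, self.introns_per_gene_sd),
            ("Exonic GC%", 100 * self.exonic_gc_mean, 100 * self.exonic_gc_sd),
            ("Intronic GC%", 100 * self.intronic_gc_mean, 100 * self.intronic_gc_sd),
        ]
        return pd.DataFrame(rows, columns=["Feature", "Average", "S.D."])


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def structure_summary(models, genome) -> StructureSummary:
    """Aggregate gene/exon/intron lengths, counts and GC across gene models.

    ``genome`` is a mapping scaffold -> sequence, a SequenceRecord, or a list
    of SequenceRecords.  Exon and intron lengths are pooled across all
    elements; counts and GC are per gene.
    """
    models = list(models)
    if not models:
        raise ValueError("no gene models")
    scaffolds = _as_scaffold_map(genome)
    exon_lengths: list[int] = []
    intron_lengths: list[int] = []
    gene_lengths: list[int] = []
    exon_counts: list[int] = []
    intron_counts: list[int] = []
    exonic_gc: list[float] = []
    intronic_gc: list[float] = []
    for m in models:
        if m.scaffold not in scaffolds:
            raise ValueError(f"{m.gene_id}: scaffold {m.scaffold!r} not in genome")
        seq = scaffolds[m.scaffold]
        if m.span[1] > len(seq):
            raise ValueError(
                f"{m.gene_id}: model extends past the end of {m.scaffold} "
                f"({m.span[1]} > {len(seq)})"
            )
        introns = derive_introns(m)
        gene_lengths.append(m.length)
        exon_counts.append(len(m.exons))
        intron_counts.append(len(introns))
        exon_lengths.extend(e - s for s, e in m.exons)
        intron_lengths.extend(e - s for s, e in introns)
        ex_seq = "".join(seq[s:e] for s, e in m.exons)
        exonic_gc.append(_gc_of(ex_seq))
        if introns:
            in_seq = "".join(seq[s:e] for s, e in introns)
            intronic_gc.append(_gc_of(in_seq))
    gl = _mean_sd(gene_lengths)
    el = _mean_sd(exon_lengths)
    il = _mean_sd(intron_lengths)
    ec = _mean_sd(exon_counts)
    ic = _mean_sd(intron_counts)
    eg = _mean_sd([g for g in exonic_gc if not np.isnan(g)])
    ig = _mean_sd([g for g in intronic_gc if not np.isnan(g)])
    return StructureSummary(
        n_genes=len(models),
        gene_length_mean=gl[0], gene_length_sd=gl[1],
        exon_length_mean=el[0], exon_length_sd=el[1],
        intron_length_mean=il[0], intron_length_sd=il[1],
        exons_per_gene_mean=ec[0], exons_per_gene_sd=ec[1],
        introns_per_gene_mean=ic[0], introns_per_gene_sd=ic[1],
        exonic_gc_mean=eg[0], exonic_gc_sd=eg[1],
        intronic_gc_mean=ig[0], intronic_gc_sd=ig[1],
    )


def _gc_of(seq: str) -> float:
    prof = per_record_gc([SequenceRecord("x", seq)])
    row = prof.records.iloc[0]
    return float(row.gc) if row.usable else float("nan")


def _as_scaffold_map(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: (v.seq if isinstance(v, SequenceRecord) else v) for k, v in genome.items()}
    if isinstance(genome, SequenceRecord):
        return {genome.id: genome.seq}
    return {r.id: r.seq for r in genome}


def first_elements(models) -> dict[str, tuple[Interval, Interval | None]]:
    """Per gene, the first exon and first intron in TRANSCRIPT orientation:
    for '-' strand genes the genomically last exon/intron is first."""
    out: dict[str, tuple[Interval, Interval | None]] = {}
    for m in models:
        introns = derive_introns(m)
        if m.strand == "+":
            fe = m.exons[0]
            fi = introns[0] if introns else None
        else:
            fe = m.exons[-1]
            fi = introns[-1] if introns else None
        out[m.gene_id] = (fe, fi)
    return out


@dataclass(frozen=True)
class StructureExpressionReport:
    organ: str
    n: int
    top_ids: tuple[str, ...]
    bottom_ids: tuple[str, ...]
    top_intron_mean: float
    top_intron_sd: float
    bottom_intron_mean: float
    bottom_intron_sd: float
    top_exon_mean: float
    top_exon_sd: float
    bottom_exon_mean: float
    bottom_exon_sd: float
    per_gene: pd.DataFrame = field(repr=False)


def structure_vs_expression(
    models, expression, organ: str, n: int = 10, id_filter=None
) -> StructureExpressionReport:
    """Compare exon/intron sizes of the n most vs least expressed genes.

    Genes are ranked by FPKM in ``organ`` (descending; ties broken by gene
    id).  ``id_filter``, when given, restricts the ranking to those ids (the
    draft-genome analysis restricted to KEGG-Orthology-assigned genes; any id
    list can stand in).  Exon and intron sizes are pooled over the genes of
    each set.
    """
    by_id = {m.gene_id: m for m in models}
    df = expression.fpkm if hasattr(expression, "fpkm") else expression
    if organ not in df.columns:
        raise ValueError(f"organ {organ!r} not in expression table")
    ids = [g for g in df.index if g in by_id]
    if id_filter is not None:
        allowed = set(id_filter)
        ids = [g for g in ids if g in allowed]
    if len(ids) < 2 * n:
        raise ValueError(
            f"need at least {2 * n} genes present in both the models and the "
            f"expression table, got {len(ids)}"
        )
    fpkm = df.loc[ids, organ]
    ranked = sorted(ids, key=lambda g: (-fpkm[g], g))
    top = tuple(ranked[:n])
    bottom = tuple(ranked[-n:])

    def _sizes(gene_ids):
        ex, intr = [], []
        for g in gene_ids:
            m = by_id[g]
            ex.extend(e - s for s, e in m.exons)
            intr.extend(e - s for s, e in derive_introns(m))
        return ex, intr

    top_ex, top_in = _sizes(top)
    bot_ex, bot_in = _sizes(bottom)
    rows = []
    for label, gene_ids in (("top", top), ("bottom", bottom)):
        for g in gene_ids:
            m = by_id[g]
            introns = derive_introns(m)
            rows.append(
                (
                    g, label, float(fpkm[g]), len(m.exons),
                    sum(e - s for s, e in m.exons),
                    sum(e - s for s, e in introns),
                    ";".join(f"{s}-{e}" for s, e in m.exons),
                )
            )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "set", "fpkm", "n_exons",
            "total_exon_bp", "total_intron_bp", "exons",
        ],
    )
    ti, tis = _mean_sd(top_in)
    bi, bis = _mean_sd(bot_in)
    te, tes = _mean_sd(top_ex)
    be, bes = _mean_sd(bot_ex)
    return StructureExpressionReport(
        organ=organ, n=n, top_ids=top, bottom_ids=bottom,
        top_intron_mean=ti, top_intron_sd=tis,
        bottom_intron_mean=bi, bottom_intron_sd=bis,
        top_exon_mean=te, top_exon_sd=tes,
        bottom_exon_mean=be, bottom_exon_sd=bes,
        per_gene=per_gene,
    )
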