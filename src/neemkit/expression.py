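"""FPKM transforms, GC-binned expression, EF1A-normalised cross-species
differential indices, and top/bottom transcript selection.

FPKM (fragments per kilobase of transcript per million mapped fragments) is a
within-sample abundance; cross-species comparison therefore first normalises
every gene's abundance to that of the housekeeping gene EF1A (elongation
factor 1-alpha) in the same column, making the differential index

    D(g) = log2[ (FPKM_g / FPKM_EF1A)_ref / (FPKM_g / FPKM_EF1A)_other ]

invariant to per-column rescaling, zero for EF1A itself, and antisymmetric
under swapping the two species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x organ (or species) FPKM matrix; cells finite and >= 0."""

    fpkm: pd.DataFrame = field(repr=False)
    ef1a_id: str | None = None

    def __post_init__(self):
        df = self.fpkm
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression table contains non-finite cells")
        if (values < 0).any():
            raise ValueError("FPKM must be >= 0")
        if self.ef1a_id is not None and self.ef1a_id not in df.index:
            raise ValueError(f"designated EF1A id {self.ef1a_id!r} not in table")

    @property
    def organs(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fpkm.shape

    def to_tsv(self, path) -> None:
        self.fpkm.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class Log2Result:
    values: pd.DataFrame = field(repr=False)  # NaN where a zero cell was dropped
    n_dropped: int = 0
    policy: str = "drop"


def log2_fpkm(table: ExpressionTable, zero_policy: str = "drop",
              pseudocount: float | None = None) -> Log2Result:
    """log2-transform FPKM.  ``drop``: zero cells become NaN and are counted;
    ``pseudocount``: log2(FPKM + c) with c > 0."""
    df = table.fpkm
    if zero_policy == "drop":
        zeros = int((df.to_numpy() == 0).sum())
        out = np.log2(df.where(df > 0))
        return Log2Result(values=out, n_dropped=zeros, policy="drop")
    if zero_policy == "pseudocount":
        if pseudocount is None or pseudocount <= 0:
            raise ValueError("pseudocount policy requires c > 0")
        return Log2Result(values=np.log2(df + pseudocount), n_dropped=0,
                          policy=f"pseudocount:{pseudocount}")
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


@dataclass(frozen=True)
class GCBinnedExpression:
    gc_bin: float
    expr_bin: float
    histograms: dict[float, pd.DataFrame] = field(repr=False)
    max_density_cell: tuple[tuple[float, float], tuple[float, float]] = ((0, 0), (0, 0))
    n_included: int = 0
    n_dropped_zero: int = 0


def gc_binned_expression(
    table: ExpressionTable,
    transcript_gc,
    gc_bin: float = 0.20,
    expr_bin: float = 0.5,
    organ: str | None = None,
) -> GCBinnedExpression:
    """Per-GC-bin histograms of log2 FPKM (zero cells dropped and counted).

    GC bins are half-open lower-inclusive ([0, 0.2), [0.2, 0.4), ...).  When
    ``organ`` is None all columns are pooled.  Reports the (gc-bin,
    expression-bin) cell of maximum count.
    """
    prof = transcript_gc.records if hasattr(transcript_gc, "records") else transcript_gc
    gc_by_id = dict(zip(prof["id"], prof["gc"]))
    missing = [g for g in table.gene_ids if g not in gc_by_id]
    if missing:
        raise ValueError(f"ids missing from GC profile: {missing[:10]}")
    df = table.fpkm if organ is None else table.fpkm[[organ]]
    n_zero = 0
    values_by_bin: dict[float, list[float]] = {}
    for gene in df.index:
        gc = gc_by_id[gene]
        lo = np.floor(gc / gc_bin) * gc_bin
        for v in df.loc[gene]:
            if v == 0:
                n_zero += 1
                continue
            values_by_bin.setdefault(round(float(lo), 10), []).append(np.log2(v))
    histograms: dict[float, pd.DataFrame] = {}
    best = (0, None, None)
    n_included = 0
    for lo, vals in sorted(values_by_bin.items()):
        arr = np.asarray(vals)
        n_included += arr.size
        emin = np.floor(arr.min() / expr_bin) * expr_bin
        emax = np.floor(arr.max() / expr_bin) * expr_bin + expr_bin
        edges = np.arange(emin, emax + expr_bin / 2, expr_bin)
        counts, _ = np.histogram(arr, bins=edges)
        histograms[lo] = pd.DataFrame({"bin_lower": edges[:-1], "count": counts})
        i = int(np.argmax(counts))
        if counts[i] > best[0]:
            best = (int(counts[i]), lo, float(edges[i]))
    if best[1] is None:
        raise ValueError("no nonzero expression values to bin")
    cell = (
        (best[1], round(best[1] + gc_bin, 10)),
        (best[2], best[2] + expr_bin),
    )
    return GCBinnedExpression(
        gc_bin=gc_bin,
        expr_bin=expr_bin,
        histograms=histograms,
        max_density_cell=cell,
        n_included=n_included,
        n_dropped_zero=n_zero,
    )


def ef1a_normalize(table: ExpressionTable, ef1a_id: str | None = None) -> ExpressionTable:
    """Divide every column by its EF1A cell; the EF1A row becomes all 1."""
    ef1a = ef1a_id or table.ef1a_id
    if ef1a is None:
        raise ValueError("no EF1A id designated")
    if ef1a not in table.fpkm.index:
        raise ValueError(f"EF1A id {ef1a!r} missing from table")
    ref = table.fpkm.loc[ef1a]
    zero_cols = [c for c in table.fpkm.columns if ref[c] <= 0]
    if zero_cols:
        raise ValueError(f"EF1A has zero FPKM in column(s) {zero_cols}")
    return ExpressionTable(fpkm=table.fpkm / ref, ef1a_id=ef1a)


@dataclass(frozen=True)
class DifferentialIndexResult:
    organ: str
    indices: pd.DataFrame = field(repr=False)  # ref_id, other_id, index
    excluded_zero: tuple[str, ...] = ()
    unmapped: tuple[str, ...] = ()

    def cumulative(self) -> pd.DataFrame:
        """Indices sorted ascending with a cumulative count (bar-chart data)."""
        s = self.indices.sort_values("index").reset_index(drop=True)
        s["cumulative_n"] = np.arange(1, len(s) + 1)
        return s


def differential_index(
    ref_table: ExpressionTable,
    other_table: ExpressionTable,
    ortholog_map: pd.DataFrame,
    ef1a_ref: str | None = None,
    ef1a_other: str | None = None,
    organ: str = "leaf",
) -> DifferentialIndexResult:
    """log2 ratio of EF1A-normalised abundances between two species.

    ``ortholog_map`` has columns ref_id, other_id.  Genes absent from either
    table are skipped (reported); genes with zero normalised abundance in
    either species are excluded (reported).  An all-unmapped input is an
    error.
    """
    ref_n = ef1a_normalize(ref_table, ef1a_ref)
    oth_n = ef1a_normalize(other_table, ef1a_other)
    for name, t in (("reference", ref_n), ("other", oth_n)):
        if organ not in t.fpkm.columns:
            raise ValueError(f"organ {organ!r} missing from {name} table")
    rows = []
    excluded: list[str] = []
    unmapped: list[str] = []
    for rec in ortholog_map.itertuples():
        rid, oid = rec.ref_id, rec.other_id
        if rid not in ref_n.fpkm.index or oid not in oth_n.fpkm.index:
            unmapped.append(rid)
            continue
        a = ref_n.fpkm.at[rid, organ]
        b = oth_n.fpkm.at[oid, organ]
        if a <= 0 or b <= 0:
            excluded.append(rid)
            continue
        rows.append((rid, oid, float(np.log2(a / b))))
    if not rows and unmapped:
        raise ValueError("no ortholog pair maps into both tables")
    indices = pd.DataFrame(rows, columns=["ref_id", "other_id", "index"])
    return DifferentialIndexResult(
        organ=organ,
        indices=indices,
        excluded_zero=tuple(excluded),
        unmapped=tuple(unmapped),
    )


def top_bottom(
    table: ExpressionTable, organ: str, n: int
) -> tuple[list[str], list[str], pd.DataFrame]:
    """The n most and least expressed gene ids in ``organ`` (ties broken by
    id), plus a heat-map-ready log2(FPKM + 1) matrix for their union."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if organ not in table.fpkm.columns:
        raise ValueError(f"organ {organ!r} not in table")
    if len(table.fpkm) < 2 * n:
        raise ValueError(f"need at least {2 * n} genes, got {len(table.fpkm)}")
    fpkm = table.fpkm[organ]
    ranked = sorted(table.gene_ids, key=lambda g: (-fpkm[g], g))
    top, bottom = ranked[:n], ranked[-n:]
    union = list(dict.fromkeys(top + bottom))
    matrix = np.log2(table.fpkm.loc[union] + 1.0)
    return top, bottom, matrix


def unannotated_top_loci(
    table: ExpressionTable,
    annotation_flags,
    locus_map,
    n: int = 300,
) -> tuple[set[str], pd.DataFrame]:
    """Per organ, the n highest-FPKM unannotated transcripts; union across
    organs collapsed to unique loci.

    ``annotation_flags``: mapping transcript id -> bool (True = annotated).
    ``locus_map``: mapping transcript id -> locus id.  Returns (unique loci,
    log2(FPKM + 1) matrix over the selected transcripts).
    """
    flags = dict(annotation_flags)
    loci = dict(locus_map)
    unannotated = [g for g in table.gene_ids if not flags.get(g, False)]
    selected: list[str] = []
    for organ in table.organs:
        fpkm = table.fpkm[organ]
        ranked = sorted(unannotated, key=lambda g: (-fpkm[g], g))
        selected.extend(ranked[:n])
    selected = list(dict.fromkeys(selected))
    missing = [g for g in selected if g not in loci]
    if missing:
        raise ValueError(f"transcripts lack a locus assignment: {missing[:10]}")
    unique_loci = {loci[g] for g in selected}
    matrix = (
        np.log2(table.fpkm.loc[selected] + 1.0)
        if selected
        else table.fpkm.iloc[0:0]
    )
    return unique_loci, matrix
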