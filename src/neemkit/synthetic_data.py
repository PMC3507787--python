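"""Synthetic genomes, planted LTR elements, gene models, reads and expression
tables with known ground truth.

Every analysis stage in this package is validated against data from this
module: the generator plants features whose true parameters are recorded in a
PlantedTruth ledger, and the analyses must recover them.  Defaults emulate
the draft-genome study conditions: a genome whose GC follows a two-component
(bimodal) mixture, LTR elements whose two copies diverged under an exact
Kimura 2-parameter substitution process for a known age at rate r
(expected divergence K = 2 r T), gene models with the published exon/intron
length, count and GC statistics, uniform-coverage substitution-error reads,
and log-normal FPKM tables over {root, leaf, stem, flower} containing a
designated EF1A housekeeping gene.

All randomness in an operation flows from the single ``seed`` of its spec;
identical specs yield byte-identical artifacts.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _seq
from .gene_structure import GeneModel
from .ltr_dating import LTRPair
from .seqio import SequenceRecord

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)  # order used by GC threshold draw


# ---------------------------------------------------------------------------
# Specs

@dataclass(frozen=True)
class GenomeSpec:
    length: int = 1_000_000
    gc_components: tuple[tuple[float, float], ...] = ((0.30, 0.5), (0.45, 0.5))
    segment_length: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (self.length >= self.segment_length >= 1):
            raise ValueError("need length >= segment_length >= 1")
        w = sum(w for _, w in self.gc_components)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"component weights must sum to 1, got {w}")
        for gc, _ in self.gc_components:
            if not (0.0 < gc < 1.0):
                raise ValueError(f"gc_mean must be in (0,1), got {gc}")


@dataclass(frozen=True)
class LTRPlantSpec:
    n_elements: int = 300
    ltr_length_range: tuple[int, int] = (2000, 2000)
    internal_length_range: tuple[int, int] = (2000, 5000)
    age_components: tuple[tuple[float, float, float], ...] = (
        (1e6, 2e5, 0.7),
        (6e6, 6e5, 0.2),
        (11e6, 1e6, 0.1),
    )  # (mean years, sd years, weight); modes mirror the observed age peaks
    rate_r: float = 1.3e-8
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self):
        w = sum(w for _, _, w in self.age_components)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"age weights must sum to 1, got {w}")
        if any(m < 0 for m, _, _ in self.age_components):
            raise ValueError("age means must be >= 0")
        if self.rate_r <= 0 or self.kappa <= 0:
            raise ValueError("rate_r and kappa must be positive")
        if self.n_elements < 0:
            raise ValueError("n_elements must be >= 0")


@dataclass(frozen=True)
class GeneSetSpec:
    """Defaults are the published gene-structure statistics (exon mean
    208.28 bp, intron mean 388.62 bp, 3.5 exons/gene, exonic GC 42.74%,
    intronic GC 30.04%).  Lengths are drawn log-normal (keeps them positive)
    parameterised by the stated mean/sd; exon counts are 1 + Poisson(mean-1).
    """

    n_genes: int = 5000
    exon_count_mean: float = 3.5
    exon_length_law: tuple[float, float] = (208.28, 210.62)
    intron_length_law: tuple[float, float] = (388.62, 393.41)
    exonic_gc: float = 0.4274
    intronic_gc: float = 0.3004
    seed: int = 0

    def __post_init__(self):
        if self.exon_count_mean < 1:
            raise ValueError("exon_count_mean must be >= 1")
        for name, (m, s) in (
            ("exon_length_law", self.exon_length_law),
            ("intron_length_law", self.intron_length_law),
        ):
            if m <= 0 or s < 0:
                raise ValueError(f"{name}: mean must be > 0 and sd >= 0")
        for name, gc in (("exonic_gc", self.exonic_gc), ("intronic_gc", self.intronic_gc)):
            if not (0.0 < gc < 1.0):
                raise ValueError(f"{name} must be in (0,1)")


@dataclass(frozen=True)
class ReadSimSpec:
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0.0 <= self.error_rate < 0.2):
            raise ValueError("error_rate must be in [0, 0.2)")


@dataclass(frozen=True)
class ExpressionSimSpec:
    organs: tuple[str, ...] = ("root", "leaf", "stem", "flower")
    log_fpkm_mean: float = 5.0  # log2 scale
    log_fpkm_sd: float = 2.0
    organ_noise_sd: float = 0.25
    structure_coupling: float = 0.0
    ef1a_id: str = "EF1A"
    seed: int = 0

    def __post_init__(self):
        if not self.organs:
            raise ValueError("need at least one organ")
        if not (0.0 <= self.structure_coupling <= 1.0):
            raise ValueError("structure_coupling must be in [0, 1]")
        if self.log_fpkm_sd < 0 or self.organ_noise_sd < 0:
            raise ValueError("sds must be >= 0")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth ledger for recovery tests."""

    genome_size_bp: int = 0
    segments: pd.DataFrame | None = field(default=None, repr=False)
    elements: pd.DataFrame | None = field(default=None, repr=False)
    genes: tuple[GeneModel, ...] = ()


# ---------------------------------------------------------------------------
# Genome

def generate_genome(spec: GenomeSpec) -> tuple[SequenceRecord, PlantedTruth]:
    """I.i.d. bases within fixed-length segments; each segment's GC component
    is drawn from the mixture (P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2)."""
    rng = np.random.default_rng(spec.seed)
    n_seg = -(-spec.length // spec.segment_length)
    gcs = np.array([gc for gc, _ in spec.gc_components])
    weights = np.array([w for _, w in spec.gc_components])
    comp = rng.choice(len(gcs), size=n_seg, p=weights / weights.sum())
    seg_gc = gcs[comp]
    per_base_gc = np.repeat(seg_gc, spec.segment_length)[: spec.length]
    u = rng.random(spec.length)
    # thresholds: [0, gc/2) -> G, [gc/2, gc) -> C, [gc, gc + (1-gc)/2) -> A, else T
    base_idx = (
        (u >= per_base_gc / 2).astype(np.uint8)
        + (u >= per_base_gc).astype(np.uint8)
        + (u >= per_base_gc + (1 - per_base_gc) / 2).astype(np.uint8)
    )
    seq = _BASES[base_idx].tobytes().decode("ascii")
    starts = np.arange(n_seg) * spec.segment_length
    segments = pd.DataFrame(
        {
            "start": starts,
            "end": np.minimum(starts + spec.segment_length, spec.length),
            "gc_mean": seg_gc,
            "component": comp,
        }
    )
    record = SequenceRecord("synthetic_genome", seq)
    return record, PlantedTruth(genome_size_bp=spec.length, segments=segments)


# ---------------------------------------------------------------------------
# K2P substitution process

def _k2p_event_probs(d: float, kappa: float) -> tuple[float, float]:
    """Exact K80 transition-matrix probabilities at branch length d
    (substitutions/site): returns (P(transition), P(total transversion))."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return p_ts, p_tv

_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)   # A<->G, C<->T
_TV_PARTNER1 = np.array([1, 0, 1, 0], dtype=np.uint8)  # A->C, C->A, G->C, T->A
_TV_PARTNER2 = np.array([3, 2, 3, 2], dtype=np.uint8)  # A->T, C->G, G->T, T->G


def evolve_k2p(codes: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    """Evolve base codes for branch length d under the exact K2P matrix."""
    p_ts, p_tv = _k2p_event_probs(d, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv / 2)
    tv2 = (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    out[ts] = _TS_PARTNER[codes[ts]]
    out[tv1] = _TV_PARTNER1[codes[tv1]]
    out[tv2] = _TV_PARTNER2[codes[tv2]]
    return out


# ---------------------------------------------------------------------------
# LTR elements

def plant_ltr_elements(
    genome: SequenceRecord, spec: LTRPlantSpec
) -> tuple[SequenceRecord, list[LTRPair], PlantedTruth]:
    """Insert ltr-internal-ltr elements at uniform distinct positions.

    For each element an age T is drawn from the mixture, an ancestral LTR is
    synthesised, and the 5' and 3' copies evolve independently for branch
    length r*T each under the exact K2P matrix, so their expected divergence
    is K = 2 r T.  Insertions (not overwrites) at distinct points can never
    overlap or nest.
    """
    L = len(genome.seq)
    if spec.n_elements > L + 1:
        raise ValueError(
            f"cannot place {spec.n_elements} elements in a {L} bp genome "
            "without overlap; use a larger genome"
        )
    rng = np.random.default_rng(spec.seed)
    means = np.array([m for m, _, _ in spec.age_components])
    sds = np.array([s for _, s, _ in spec.age_components])
    weights = np.array([w for _, _, w in spec.age_components])
    comp = rng.choice(len(means), size=spec.n_elements, p=weights / weights.sum())
    ages = np.maximum(rng.normal(means[comp], sds[comp]), 0.0)
    points = np.sort(rng.choice(L + 1, size=spec.n_elements, replace=False))

    pairs: list[LTRPair] = []
    chunks: list[str] = []
    truth_rows = []
    cursor = 0
    offset = 0  # accumulated inserted length before the current point
    for i in range(spec.n_elements):
        eid = f"ltr{i:04d}"
        ltr_len = int(rng.integers(spec.ltr_length_range[0], spec.ltr_length_range[1] + 1))
        int_len = int(rng.integers(spec.internal_length_range[0], spec.internal_length_range[1] + 1))
        ancestral = rng.integers(0, 4, size=ltr_len).astype(np.uint8)
        d = spec.rate_r * ages[i]
        five = evolve_k2p(ancestral, d, spec.kappa, rng)
        three = evolve_k2p(ancestral, d, spec.kappa, rng)
        internal = rng.integers(0, 4, size=int_len).astype(np.uint8)
        seq5, seq3 = _seq.decode(five), _seq.decode(three)
        element = seq5 + _seq.decode(internal) + seq3
        pairs.append(
            LTRPair(
                element_id=eid,
                five_prime=SequenceRecord(f"{eid}_5p", seq5),
                three_prime=SequenceRecord(f"{eid}_3p", seq3),
            )
        )
        p = int(points[i])
        chunks.append(genome.seq[cursor:p])
        chunks.append(element)
        pos = p + offset
        truth_rows.append(
            (
                eid, genome.id, pos, ltr_len, int_len,
                pos, pos + ltr_len + int_len,
                float(ages[i]), 2.0 * spec.rate_r * float(ages[i]),
            )
        )
        cursor = p
        offset += len(element)
    chunks.append(genome.seq[cursor:])
    new_seq = "".join(chunks)
    elements = pd.DataFrame(
        truth_rows,
        columns=[
            "element_id", "scaffold", "position", "ltr_length", "internal_length",
            "five_prime_start", "three_prime_start", "true_age_years",
            "true_expected_K",
        ],
    )
    modified = SequenceRecord(genome.id, new_seq, genome.description)
    return modified, pairs, PlantedTruth(genome_size_bp=len(new_seq), elements=elements)


# ---------------------------------------------------------------------------
# Gene models

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_lengths(rng, mean: float, sd: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if sd == 0:
        return np.full(n, max(1, round(mean)), dtype=np.int64)
    mu, sigma = _lognormal_params(mean, sd)
    return np.maximum(np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64), 1)


def _seq_at_gc(rng, n: int, gc: float) -> str:
    u = rng.random(n)
    idx = (
        (u >= gc / 2).astype(np.uint8)
        + (u >= gc).astype(np.uint8)
        + (u >= gc + (1 - gc) / 2).astype(np.uint8)
    )
    return _BASES[idx].tobytes().decode("ascii")


def plant_gene_models(
    genome: SequenceRecord, spec: GeneSetSpec, max_tries: int = 1000
) -> tuple[SequenceRecord, list[GeneModel], PlantedTruth]:
    """Overwrite non-overlapping genome intervals with genes whose exon/intron
    counts, lengths and GC follow the spec's laws; strand drawn uniformly."""
    rng = np.random.default_rng(spec.seed)
    L = len(genome.seq)
    n_exons = 1 + rng.poisson(spec.exon_count_mean - 1.0, size=spec.n_genes)
    starts_sorted: list[int] = []
    ends_sorted: list[int] = []
    out = bytearray(genome.seq, "ascii")
    models: list[GeneModel] = []
    for i in range(spec.n_genes):
        gid = f"gene{i:05d}"
        ne = int(n_exons[i])
        ex_len = _draw_lengths(rng, *spec.exon_length_law, ne)
        in_len = _draw_lengths(rng, *spec.intron_length_law, ne - 1)
        glen = int(ex_len.sum() + in_len.sum())
        if glen > L:
            raise ValueError(
                f"{gid}: gene of {glen} bp exceeds the {L} bp genome; "
                "use a larger genome"
            )
        placed = False
        for _ in range(max_tries):
            start = int(rng.integers(0, L - glen + 1))
            j = bisect.bisect_right(starts_sorted, start)
            if j > 0 and ends_sorted[j - 1] > start:
                continue
            if j < len(starts_sorted) and starts_sorted[j] < start + glen:
                continue
            bisect.insort(starts_sorted, start)
            ends_sorted.insert(j, start + glen)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place {gid} without overlap after {max_tries} tries; "
                "use a larger genome"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        pieces = []
        for k in range(ne):
            exons.append((pos, pos + int(ex_len[k])))
            pieces.append(_seq_at_gc(rng, int(ex_len[k]), spec.exonic_gc))
            pos += int(ex_len[k])
            if k < ne - 1:
                pieces.append(_seq_at_gc(rng, int(in_len[k]), spec.intronic_gc))
                pos += int(in_len[k])
        out[start : start + glen] = "".join(pieces).encode("ascii")
        models.append(
            GeneModel(gene_id=gid, scaffold=genome.id, strand=strand, exons=tuple(exons))
        )
    modified = SequenceRecord(genome.id, out.decode("ascii"), genome.description)
    return modified, models, PlantedTruth(genome_size_bp=L, genes=tuple(models))


# ---------------------------------------------------------------------------
# Reads

def simulate_reads(genome: SequenceRecord, spec: ReadSimSpec) -> list[SequenceRecord]:
    """Uniform-start single-end reads at the given fold coverage; strand
    uniform (reverse-complemented reads); i.i.d. substitution errors."""
    L = len(genome.seq)
    if spec.read_length > L:
        raise ValueError(f"read_length {spec.read_length} exceeds genome length {L}")
    rng = np.random.default_rng(spec.seed)
    n_reads = round(L * spec.depth / spec.read_length)
    codes = _seq.encode(genome.seq)
    starts = rng.integers(0, L - spec.read_length + 1, size=n_reads)
    mat = codes[starts[:, None] + np.arange(spec.read_length)[None, :]].copy()
    rev = rng.random(n_reads) < 0.5
    # reverse complement of valid codes is 3 - c; N (4) stays N
    sub = mat[rev]
    sub = np.where(sub < 4, 3 - sub, 4)[:, ::-1]
    mat[rev] = sub
    if spec.error_rate > 0:
        err = rng.random(mat.shape) < spec.error_rate
        err &= mat < 4
        shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
        mat[err] = (mat[err] + shift) % 4
    reads = []
    for i in range(n_reads):
        reads.append(SequenceRecord(f"read{i:07d}", _seq.decode(mat[i])))
    return reads


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(genes, spec: ExpressionSimSpec):
    """Log-normal FPKM per gene per organ; optional positive rank coupling of
    expression to total intron length; EF1A housekeeping row always present.

    The coupling knob targets a Spearman correlation of ``structure_coupling``
    between an organ's FPKM and total intron length via a Gaussian copula
    (latent Pearson rho = 2 sin(pi * c / 6)).
    """
    from .expression import ExpressionTable
    from .gene_structure import derive_introns

    genes = list(genes)
    if not genes:
        raise ValueError("no genes")
    ids = [m.gene_id for m in genes]
    if spec.ef1a_id in ids:
        raise ValueError(f"ef1a_id {spec.ef1a_id!r} collides with a gene id")
    rng = np.random.default_rng(spec.seed)
    n = len(genes)
    intron_total = np.array(
        [sum(e - s for s, e in derive_introns(m)) for m in genes], dtype=float
    )
    # normal scores of the intron-length ranks (ties broken by order)
    ranks = np.empty(n, dtype=float)
    order = np.argsort(intron_total, kind="stable")
    ranks[order] = np.arange(n)
    z_struct = norm.ppf((ranks + 0.5) / n)
    c = spec.structure_coupling
    rho = 2.0 * math.sin(math.pi * c / 6.0)
    eps = rng.standard_normal(n)
    z = rho * z_struct + math.sqrt(max(1.0 - rho * rho, 0.0)) * eps
    base = spec.log_fpkm_mean + spec.log_fpkm_sd * z
    organ_noise = rng.normal(0.0, spec.organ_noise_sd, size=(n, len(spec.organs)))
    log2_fpkm = base[:, None] + organ_noise
    fpkm = np.exp2(log2_fpkm)
    # EF1A: stable, highly expressed housekeeping reference
    ef1a_row = np.full(len(spec.organs), 2.0 ** (spec.log_fpkm_mean + 3.0))
    df = pd.DataFrame(
        np.vstack([fpkm, ef1a_row[None, :]]),
        index=pd.Index(ids + [spec.ef1a_id], name="gene_id"),
        columns=list(spec.organs),
    )
    return ExpressionTable(fpkm=df, ef1a_id=spec.ef1a_id)
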