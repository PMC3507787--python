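"""Date LTR-retrotransposon insertions from their 5'/3' LTR pairs.

The two long terminal repeats of a retrotransposon are identical at insertion
time and diverge afterwards, so their Kimura 2-parameter distance K converts
to an insertion age T = K / (2 r), with r the substitution rate per site per
year (default 1.3e-8).  The pipeline is: global affine-gap alignment of the
two LTR copies, K2P distance over the aligned columns with pairwise deletion
of gap/ambiguous columns, the age formula, and a half-open binned age
frequency distribution.

K2P distinguishes transitions (A<->G, C<->T; proportion P of valid columns)
from transversions (proportion Q):

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

The formula saturates when 1 - 2P - Q <= 0 or 1 - 2Q <= 0; saturated pairs
are reported and excluded from age distributions, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .seqio import SequenceRecord

DEFAULT_RATE = 1.3e-8  # substitutions / site / year

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class LTRPair:
    element_id: str
    five_prime: SequenceRecord
    three_prime: SequenceRecord

    def __post_init__(self):
        if not self.five_prime.seq or not self.three_prime.seq:
            raise ValueError(f"{self.element_id}: empty LTR sequence")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap nucleotide scoring.  A gap of length L costs
    open + (L - 1) * extend."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    n_valid_columns: int

    def __post_init__(self):
        assert len(self.aligned_a) == len(self.aligned_b)
        assert self.n_valid_columns <= len(self.aligned_a)


@dataclass(frozen=True)
class K2PDistance:
    P: float
    Q: float
    K: float
    n_valid_columns: int

    def __post_init__(self):
        assert self.P >= 0 and self.Q >= 0 and self.P + self.Q <= 1
        assert self.K >= 0


@dataclass(frozen=True)
class InsertionAge:
    element_id: str
    K: float
    r: float
    T: float


class SaturationError(ValueError):
    """K2P distance undefined: divergence beyond the formula's domain."""


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_ltr_pair(
    pair: LTRPair, scoring: AlignmentScoring = AlignmentScoring()
) -> PairwiseAlignment:
    """Optimal global (end-to-end) affine-gap alignment of the two LTR copies."""
    return align_sequences(pair.five_prime.seq, pair.three_prime.seq, scoring)


def align_sequences(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> PairwiseAlignment:
    for name, s in (("first", a), ("second", b)):
        if not s.strip("N"):
            raise ValueError(f"{name} sequence contains no unambiguous bases")
    aligner = _make_aligner(scoring)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    n_valid = sum(1 for x, y in zip(ga, gb) if x in _BASES and y in _BASES)
    return PairwiseAlignment(
        aligned_a=ga, aligned_b=gb, score=float(aln.score), n_valid_columns=n_valid
    )


def k2p_from_alignment(alignment: PairwiseAlignment) -> K2PDistance:
    """K2P distance over aligned columns, pairwise deletion of gaps/ambiguity."""
    n_valid = 0
    ts = 0
    tv = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x not in _BASES or y not in _BASES:
            continue
        n_valid += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n_valid == 0:
        raise ValueError("alignment has no valid (unambiguous, ungapped) columns")
    return k2p_from_proportions(ts / n_valid, tv / n_valid, n_valid)


def k2p_from_proportions(P: float, Q: float, n_valid: int = 0) -> K2PDistance:
    """K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]; raises SaturationError off-domain."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated: P={P:.4f}, Q={Q:.4f} "
            f"(requires 1-2P-Q > 0 and 1-2Q > 0)"
        )
    k = -0.5 * math.log(w1 * math.sqrt(w2))
    # exact-equality guard: identical sequences must give K == 0
    if P == 0 and Q == 0:
        k = 0.0
    return K2PDistance(P=P, Q=Q, K=max(k, 0.0), n_valid_columns=n_valid)


def insertion_age(K: float, r: float = DEFAULT_RATE, element_id: str = "") -> InsertionAge:
    """T = K / (2 r) years since insertion."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    if K < 0:
        raise ValueError(f"K must be non-negative, got {K}")
    return InsertionAge(element_id=element_id, K=K, r=r, T=K / (2.0 * r))


@dataclass(frozen=True)
class AgeDistribution:
    """Half-open binned frequency distribution of insertion ages."""

    bin_width: float
    bins: dict[float, int] = field(repr=False)
    n_elements: int = 0
    max_age: float = 0.0
    modal_bin: float = 0.0

    def __post_init__(self):
        assert sum(self.bins.values()) == self.n_elements


def age_distribution(ages, bin_width: float = 500_000.0) -> AgeDistribution:
    """Bin ages into [i*w, (i+1)*w); reports the oldest age and modal bin."""
    ages = np.asarray([a.T if isinstance(a, InsertionAge) else a for a in ages], dtype=float)
    if ages.size == 0:
        raise ValueError("no ages to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    idx = np.floor(ages / bin_width).astype(np.int64)
    uniq, counts = np.unique(idx, return_counts=True)
    bins = {float(i * bin_width): int(c) for i, c in zip(uniq, counts)}
    modal = float(uniq[np.argmax(counts)] * bin_width)
    return AgeDistribution(
        bin_width=float(bin_width),
        bins=bins,
        n_elements=int(ages.size),
        max_age=float(ages.max()),
        modal_bin=modal,
    )


def date_ltr_pairs(
    pairs,
    r: float = DEFAULT_RATE,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[pd.DataFrame, list[str]]:
    """Align, compute K2P and age for each pair.

    Returns (table, saturated_ids): the table has one row per dated element
    (element_id, P, Q, K, T_years); saturated pairs are excluded from the
    table and listed separately.
    """
    rows = []
    saturated: list[str] = []
    for pair in pairs:
        aln = align_ltr_pair(pair, scoring)
        try:
            dist = k2p_from_alignment(aln)
        except SaturationError:
            saturated.append(pair.element_id)
            continue
        age = insertion_age(dist.K, r, element_id=pair.element_id)
        rows.append((pair.element_id, dist.P, dist.Q, dist.K, age.T))
    table = pd.DataFrame(rows, columns=["element_id", "P", "Q", "K", "T_years"])
    return table, saturated
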