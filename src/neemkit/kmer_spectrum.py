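"""Canonical k-mer spectrum from reads and genome-size estimation.

The spectrum is the histogram c_m = number of distinct canonical k-mers seen
with multiplicity m.  For error-bearing reads c_m has an error peak at m = 1
falling into a valley at m_min, then a coverage peak at m_peak near the
per-k-mer coverage depth.  Genome size is estimated as

    G = (sum over m >= m_min of m * c_m) / m_peak,

i.e. total non-error k-mer instances divided by the coverage-peak
multiplicity.  Counting is canonical (a k-mer is merged with its reverse
complement, keyed by the lexicographically smaller of the two), so k must be
odd to rule out self-complementary k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seq


@dataclass(frozen=True)
class KmerSpectrum:
    """Multiplicity histogram of canonical k-mers: histogram[m] = c_m."""

    k: int
    histogram: dict[int, int] = field(repr=False)

    @property
    def total_instances(self) -> int:
        """Sum of m * c_m == number of valid k-mer windows counted."""
        return sum(m * c for m, c in self.histogram.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.histogram.values())


@dataclass(frozen=True)
class GenomeSizeEstimate:
    error_valley: int
    coverage_peak: int
    genome_size_bp: float
    k: int

    def __post_init__(self):
        assert self.coverage_peak >= self.error_valley >= 1
        assert self.genome_size_bp > 0


def count_kmer_spectrum(reads, k: int = 17) -> KmerSpectrum:
    """Count canonical k-mers over all reads (windows with N skipped)."""
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if k % 2 == 0:
        raise ValueError(
            f"k must be odd (even k admits self-complementary k-mers), got {k}"
        )
    seqs = [r.seq for r in reads]
    if not seqs:
        raise ValueError("no reads")
    if all(len(s) < k for s in seqs):
        raise ValueError(f"k={k} exceeds every read length")
    codes = _seq.concat_with_separators(seqs)
    fwd, valid = _seq.window_kmer_codes(codes, k)
    rc = _seq.window_rc_codes(codes, k)
    canonical = np.minimum(fwd, rc)[valid]
    _, per_kmer = np.unique(canonical, return_counts=True)
    mults, n_distinct = np.unique(per_kmer, return_counts=True)
    histogram = {int(m): int(c) for m, c in zip(mults, n_distinct)}
    return KmerSpectrum(k=k, histogram=histogram)


class SpectrumShapeError(ValueError):
    """The spectrum has no usable coverage peak."""


def estimate_genome_size(spectrum: KmerSpectrum) -> GenomeSizeEstimate:
    """Locate the error valley and coverage peak, then divide instances by
    peak multiplicity.

    The valley m_min is the first local minimum of c_m scanning the present
    multiplicities in ascending order (plateau ties break toward smaller m);
    if c at the smallest multiplicity is not a local maximum there is no error
    peak and m_min = 1.  The peak is the argmax of c_m over m >= m_min.
    """
    if not spectrum.histogram:
        raise ValueError("empty spectrum")
    ms = np.array(sorted(spectrum.histogram), dtype=np.int64)
    cs = np.array([spectrum.histogram[int(m)] for m in ms], dtype=np.int64)
    if ms.size == 1:
        raise SpectrumShapeError(
            "spectrum lacks coverage peak; depth too low or error rate too high"
        )
    if cs[0] < cs[1]:
        m_min = int(ms[0])
        i_min = 0
    else:
        i_min = None
        for i in range(1, ms.size):
            left_ok = cs[i] <= cs[i - 1]
            right_ok = i == ms.size - 1 or cs[i] <= cs[i + 1]
            if left_ok and right_ok and i < ms.size - 1:
                i_min = i
                break
        if i_min is None:
            raise SpectrumShapeError(
                "spectrum lacks coverage peak; depth too low or error rate too high"
            )
        m_min = int(ms[i_min])
    tail = slice(i_min, None)
    i_peak = i_min + int(np.argmax(cs[tail]))
    m_peak = int(ms[i_peak])
    if i_peak == i_min and i_min > 0:
        # peak collapsed onto the valley: flat or decreasing tail
        raise SpectrumShapeError(
            "spectrum lacks coverage peak; depth too low or error rate too high"
        )
    instances = int(np.sum(ms[tail] * cs[tail]))
    return GenomeSizeEstimate(
        error_valley=m_min,
        coverage_peak=m_peak,
        genome_size_bp=instances / m_peak,
        k=spectrum.k,
    )
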