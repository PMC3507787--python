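"""Single-strand k-mer reverse-complement symmetry (Chargaff's second parity
rule) as an assembly-QC statistic.

Within a single DNA strand the count of a word w approximately equals that of
its reverse complement w̄; the ratio S(w) = f(w) / (f(w) + f(w̄)) deviating
from 0.5 measures strand asymmetry.  Counting here is deliberately
single-strand — no canonicalisation — unlike the coverage-oriented k-mer
spectrum module.  Palindromic k-mers (w == w̄, possible only at even k) have
S = 0.5 by construction and are flagged and excluded from dispersion
summaries so they cannot artificially tighten a distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .seqio import SequenceRecord


def strand_kmer_counts(records, k: int) -> dict[str, int]:
    """Count length-k windows on the given strand only, pooled over records.

    Windows containing N are skipped.  Returns observed k-mer -> count.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seqs = [r.seq for r in records]
    if not seqs:
        raise ValueError("no records")
    if all(len(s) < k for s in seqs):
        raise ValueError(f"k={k} is larger than every record")
    codes = _seq.concat_with_separators(seqs)
    kmers, valid = _seq.window_kmer_codes(codes, k)
    vals, counts = np.unique(kmers[valid], return_counts=True)
    return {
        _seq.kmer_code_to_str(int(v), k): int(c) for v, c in zip(vals, counts)
    }


@dataclass(frozen=True)
class SymmetryTable:
    """Per complement-pair symmetry ratios at a fixed k.

    ``pairs`` columns: w (lexicographically smaller member), w_rc, f_w,
    f_wbar, S = f_w/(f_w+f_wbar), palindrome flag.  Pairs with zero total are
    excluded and counted in ``n_zero_pairs``.
    """

    k: int
    pairs: pd.DataFrame = field(repr=False)
    n_zero_pairs: int = 0


def symmetry_table(counts: dict[str, int], k: int) -> SymmetryTable:
    """Build the per-pair symmetry table from single-strand counts."""
    seen: set[str] = set()
    rows = []
    n_zero = 0
    keys = set(counts)
    keys |= {_seq.revcomp(w) for w in keys}
    for w in sorted(keys):
        wbar = _seq.revcomp(w)
        lo = min(w, wbar)
        if lo in seen:
            continue
        seen.add(lo)
        hi = _seq.revcomp(lo)
        f_w = counts.get(lo, 0)
        f_wbar = counts.get(hi, 0)
        pal = lo == hi
        if pal:
            s = 0.5
        elif f_w + f_wbar == 0:
            n_zero += 1
            continue
        else:
            s = f_w / (f_w + f_wbar)
        rows.append((lo, hi, f_w, f_wbar, s, pal))
    df = pd.DataFrame(
        rows, columns=["w", "w_rc", "f_w", "f_wbar", "S", "palindrome"]
    )
    return SymmetryTable(k=k, pairs=df, n_zero_pairs=n_zero)


@dataclass(frozen=True)
class SymmetrySummary:
    """Dispersion of S over non-palindromic pairs with nonzero totals."""

    k: int
    eps: float
    n_pairs: int
    mean_S: float
    median_S: float
    sd_S: float
    fraction_within_eps: float
    histogram: pd.DataFrame = field(repr=False)


def summarize_symmetry(
    table: SymmetryTable, eps: float = 0.01, hist_bin: float = 0.01
) -> SymmetrySummary:
    """Summarise a SymmetryTable: mean/median/sd of S and the fraction of
    pairs with |S - 0.5| <= eps, palindromes excluded."""
    s = table.pairs.loc[~table.pairs.palindrome, "S"].to_numpy()
    if s.size == 0:
        raise ValueError("no non-palindromic pairs with nonzero counts")
    edges = np.arange(0.0, 1.0 + hist_bin, hist_bin)
    counts, _ = np.histogram(s, bins=edges)
    hist = pd.DataFrame({"bin_lower": edges[:-1], "count": counts})
    return SymmetrySummary(
        k=table.k,
        eps=eps,
        n_pairs=int(s.size),
        mean_S=float(np.mean(s)),
        median_S=float(np.median(s)),
        sd_S=float(np.std(s, ddof=1)) if s.size > 1 else 0.0,
        fraction_within_eps=float(np.mean(np.abs(s - 0.5) <= eps)),
        histogram=hist,
    )


def compare_symmetry(summary_a: SymmetrySummary, summary_b: SymmetrySummary) -> dict:
    """Compare two assemblies' symmetry dispersion; smaller sd_S is 'tighter'."""
    if summary_a.k != summary_b.k:
        raise ValueError(f"mismatched k: {summary_a.k} vs {summary_b.k}")
    if summary_a.eps != summary_b.eps:
        raise ValueError(f"mismatched eps: {summary_a.eps} vs {summary_b.eps}")
    if summary_a.sd_S < summary_b.sd_S:
        tighter = "A"
    elif summary_b.sd_S < summary_a.sd_S:
        tighter = "B"
    else:
        tighter = "equal"
    return {
        "k": summary_a.k,
        "eps": summary_a.eps,
        "sd_S_A": summary_a.sd_S,
        "sd_S_B": summary_b.sd_S,
        "fraction_within_eps_A": summary_a.fraction_within_eps,
        "fraction_within_eps_B": summary_b.fraction_within_eps,
        "tighter": tighter,
    }
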