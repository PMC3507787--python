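# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates, alphabets, I/O

All intervals are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary, in both directions.  Sequences are uppercase
over {A, C, G, T, N}; characters outside that alphabet are rejected by
default or mapped to N behind an explicit flag.  Lowercase (soft-masking)
information is discarded on read, and FASTQ qualities are validated but not
stored — no downstream stage consumes them.  N50/N90 are defined as the
length of the sequence at which the descending cumulative length first
reaches 50%/90% of the assembly total, with plateau ties resolved by the
first sequence reaching the threshold.

## k-mer spectrum and genome size

Counting is canonical: each window of length k (default 17, odd so that no
k-mer is its own reverse complement) is merged with its reverse complement
and keyed by the lexicographically smaller of the two.  Windows containing N
are skipped.  The spectrum c_m counts distinct canonical k-mers at each
multiplicity m.

The size estimate is a declared convention, chosen for transparency over
model fitting:

- the error valley m_min is the first local minimum of c_m scanning the
  *present* multiplicities in ascending order (plateau ties toward smaller
  m); if c at the smallest multiplicity is not a local maximum there is no
  error peak and m_min is that smallest multiplicity;
- the coverage peak m_peak is the argmax of c_m over m ≥ m_min;
- genome size = (Σ_{m ≥ m_min} m·c_m) / m_peak.

Dividing by the modal (integer) multiplicity rather than a fitted mean
coverage biases the estimate upward by roughly half a coverage unit —
about 1–2% at 25–30× k-mer coverage, visible in the worked example.  A
monotone-decreasing spectrum (depth too low, or error rate too high to leave
a coverage peak) is an error, not a silent estimate.  Heterozygosity- and
repeat-aware mixture modelling of the spectrum is out of scope.

## Chargaff second-parity symmetry

Counting here is single-strand — Chargaff's second parity rule is a
statement about one strand — which is deliberately the opposite of the
spectrum module's canonical counting.  For each complement pair {w, w̄} the
ratio S(w) = f(w)/(f(w)+f(w̄)) is reported, keyed by the lexicographically
smaller member.  Palindromic k-mers (16 of 256 at k = 4) have S = 0.5
identically and are flagged in the table but excluded from dispersion
summaries, since including them would artificially tighten any distribution.
Pairs with zero total are excluded and counted.  "Tighter" in two-assembly
comparisons means smaller sample SD of S; the fraction of pairs with
|S − 0.5| ≤ ε (default ε = 0.01) is reported alongside, and ties are
reported as equal.  A useful exact identity used by the validation suite: a
sequence concatenated with its own reverse complement is its own reverse
complement, so *every* pair — including windows spanning the junction — has
S exactly 0.5.

## LTR insertion dating

Each element's 5′ and 3′ LTR copies are aligned globally (end-to-end) under
affine-gap scoring: match +5, mismatch −4, gap open 10, gap extend 0.5,
where a gap of length L costs open + (L−1)·extend and end gaps are charged
like internal ones.  LTR pairs are near-identical, so the scoring choice is
second-order; the suite checks the aligner against an exhaustive enumeration
oracle on short sequences.  Columns with a gap or ambiguous base in either
row are removed (pairwise deletion).  Over the remaining columns, P is the
transition proportion (A↔G, C↔T), Q the transversion proportion, and

    K = −½ ln[(1 − 2P − Q) · √(1 − 2Q)].

When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 the distance is saturated: the pair is excluded
from age distributions and reported, never clamped, since clamping would
fabricate ages.  Ages are T = K/(2r) with r = 1.3×10⁻⁸
substitutions/site/year by default (overridable).  Age histograms use
half-open bins of 0.5 My from 0 and report the oldest age and modal bin.
Note that K ≈ 0.347 corresponds to T ≈ 13.35 My at the default rate — close
to the saturation boundary for strongly transition-biased divergence, which
is why saturation is surfaced rather than hidden.

## Composition and gene structure

Per-record GC excludes N from numerator and denominator; all-N records are
flagged, not fatal.  Density curves are Gaussian KDEs with Silverman's-rule
bandwidth by default (exposed), evaluated on a fixed grid in [0,1] next to a
plain histogram; modes are strict local maxima with prominence at least 5%
of the maximum density (a documented noise floor), in descending density
order.  A zero-variance input is handled as a point mass with a single mode.

Gene models are stranded tuples of non-overlapping exon intervals; introns
are the gaps between consecutive exons, so zero-length gaps are rejected at
model construction.  Summary statistics use sample SD (ddof = 1).  Exon and
intron lengths are pooled across elements; exonic/intronic GC is computed
per gene over the concatenated exonic (resp. intronic) sequence and then
averaged across genes — declared because this differs from pooled-bp GC when
lengths vary.  "First" exon/intron is in transcript orientation: for minus-
strand genes the genomically last element.  The most-/least-expressed
comparison ranks genes by FPKM in one designated organ with ties broken by
gene id, and pools the individual exon/intron sizes of each set; an optional
id-list filter stands in for annotation-based gene subsets.

## Expression

Zero-FPKM cells default to drop-and-report under log₂ transforms; a
pseudocount policy is exposed.  GC bins are width 0.20 with half-open
lower-inclusive edges; expression bins default to 0.5 log₂ units.
EF1A normalisation divides each column by its EF1A cell, making the
cross-species differential index log₂ of the ratio of normalised abundances
— exactly zero for EF1A, antisymmetric under species swap, and invariant to
per-column rescaling (the first identity is exact in floating point; the
other two hold to rounding error, ~1e-15).  Ortholog mapping is an input
table; no homology search is performed.  Differential indices default to the
leaf column; heat-map matrices use log₂(FPKM + 1) so that zero cells remain
representable.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the analyses are validated
under:

- **Genome**: i.i.d. bases within 1 kb segments whose GC component is drawn
  from a two-component mixture, default means 0.30/0.45 at equal weight —
  a minimal model of a bimodal genome-wide GC landscape.
- **LTR elements**: ancestral LTR drawn uniformly at GC 0.5, the two copies
  evolved *independently* for branch length r·T each under the exact K2P
  transition matrix (kappa default 2.0, a generic plant-like
  transition/transversion rate ratio; the elements' true value is unknown,
  so it is a parameter, not an inference).  Using the exact matrix rather
  than a small-distance Bernoulli approximation keeps planted ages unbiased
  to ~15 My.  Expected divergence is exactly 2rT, recorded per element.
  The default age mixture has components at 1/6/11 My with weights
  0.7/0.2/0.1 and sds 0.2/0.6/1.0 My — sds chosen once so the components
  are distinguishable in a 0.5 My histogram while remaining genuinely
  dispersed.  Elements are *inserted* (not overwritten) at distinct uniform
  points, so they can never overlap or nest.
- **Genes**: exon counts 1 + Poisson(mean − 1) (default mean 3.5); exon and
  intron lengths log-normal parameterised by the published mean/SD pairs
  (208.28/210.62 and 388.62/393.41 bp) — the log-normal family is a choice,
  made to keep lengths positive, as only mean and SD are published; exonic
  and intronic sequence written at GC 0.4274/0.3004 by direct composition
  sampling.  Genes overwrite non-overlapping genome intervals.
- **Reads**: single-end, uniform starts, uniform strand, i.i.d. substitution
  errors; read count = round(genome × depth / read length).
- **Expression**: gene-level log₂ FPKM ~ Normal(5.0, 2.0) plus organ noise
  (sd 0.25), exponentiated; the structure-coupling knob couples expression
  rank to total intron length through a Gaussian copula with latent
  correlation ρ = 2·sin(π·c/6), targeting Spearman correlation c.  EF1A is
  a constant, highly expressed row (log₂ FPKM = mean + 3) present in every
  organ.

Not emulated: indels and nested/solo LTR elements, target-site
duplications, paired-end reads and realistic quality profiles, isoforms and
UTR/CDS structure, GC isochore autocorrelation, and organ-specific
expression programmes beyond i.i.d. noise.  Passing recovery tests therefore
demonstrates the *estimators* are correct under their stated models, not
that real genomes satisfy those models; on real data, indel-rich or nested
elements and heterozygosity will add error the synthetic benchmarks do not
show.

## Problem sizes and determinism

The validation suite runs the full pipelines at deliberately compact scales
chosen to exercise every code path with tight statistical tolerances: 200 kb
genomes at 30× for spectrum recovery, 300 planted 2 kb-LTR elements for age
recovery, 5,000 genes for structure round-trips, 20-seed replication for
coupling detection.  Every generator draws all randomness from the single
seed in its spec, and identical spec + seed reproduces byte-identical
artifacts; the CLI derives stage seeds deterministically from its one
`--seed` flag.
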