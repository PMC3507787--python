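"""Planted-truth generators: determinism, ground-truth consistency, and
statistical properties of the emitted artifacts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from neemkit import (
    ExpressionSimSpec,
    GeneSetSpec,
    GenomeSpec,
    LTRPlantSpec,
    ReadSimSpec,
    SequenceRecord,
    generate_genome,
    per_record_gc,
    plant_gene_models,
    plant_ltr_elements,
    simulate_expression,
    simulate_reads,
)
from neemkit.gene_structure import derive_introns
from neemkit.synthetic_data import evolve_k2p
from neemkit._seq import encode, revcomp


class TestGenerateGenome:
    def test_single_component_gc(self):
        genome, _ = generate_genome(
            GenomeSpec(length=10_000, gc_components=((0.5, 1.0),), seed=1)
        )
        gc = per_record_gc([genome]).records.gc.iloc[0]
        assert abs(gc - 0.5) < 0.03  # ~6 binomial sds

    def test_two_component_segment_modes(self):
        spec = GenomeSpec(
            length=500_000,
            gc_components=((0.30, 0.5), (0.45, 0.5)),
            segment_length=1000,
            seed=2,
        )
        genome, truth = generate_genome(spec)
        seg_gc = []
        for row in truth.segments.itertuples():
            codes = encode(genome.seq[row.start : row.end])
            seg_gc.append(np.mean((codes == 1) | (codes == 2)))
        seg_gc = np.array(seg_gc)
        lo = seg_gc[truth.segments.gc_mean.values == 0.30]
        hi = seg_gc[truth.segments.gc_mean.values == 0.45]
        assert abs(lo.mean() - 0.30) < 0.005
        assert abs(hi.mean() - 0.45) < 0.005

    def test_determinism(self):
        spec = GenomeSpec(length=20_000, seed=3)
        g1, _ = generate_genome(spec)
        g2, _ = generate_genome(spec)
        assert g1.seq == g2.seq

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            GenomeSpec(length=100, gc_components=((0.5, 0.6),))
        with pytest.raises(ValueError):
            GenomeSpec(length=10, segment_length=100)


class TestEvolveK2P:
    def test_zero_branch_identity(self, rng):
        codes = rng.integers(0, 4, 1000).astype(np.uint8)
        assert np.array_equal(evolve_k2p(codes, 0.0, 2.0, rng), codes)

    def test_divergence_matches_branch_length(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, 200_000).astype(np.uint8)
        d = 0.1
        evolved = evolve_k2p(codes, d, 2.0, rng)
        # observed proportion differing ~= P(ts) + P(tv) at branch length d
        from neemkit.synthetic_data import _k2p_event_probs

        p_ts, p_tv = _k2p_event_probs(d, 2.0)
        observed = np.mean(evolved != codes)
        assert observed == pytest.approx(p_ts + p_tv, rel=0.02)


class TestPlantLTR:
    def test_zero_age_identical_copies(self):
        genome, _ = generate_genome(GenomeSpec(length=50_000, seed=6))
        _, pairs, _ = plant_ltr_elements(
            genome,
            LTRPlantSpec(
                n_elements=5,
                ltr_length_range=(300, 300),
                internal_length_range=(200, 200),
                age_components=((0.0, 0.0, 1.0),),
                seed=7,
            ),
        )
        for p in pairs:
            assert p.five_prime.seq == p.three_prime.seq

    def test_truth_expected_k_is_2rT(self):
        genome, _ = generate_genome(GenomeSpec(length=50_000, seed=6))
        spec = LTRPlantSpec(n_elements=10, ltr_length_range=(200, 400),
                            internal_length_range=(100, 200), seed=8)
        _, _, truth = plant_ltr_elements(genome, spec)
        np.testing.assert_allclose(
            truth.elements.true_expected_K,
            2 * spec.rate_r * truth.elements.true_age_years,
        )

    def test_truth_coordinates_reproduce_planted_sequences(self):
        genome, _ = generate_genome(GenomeSpec(length=30_000, seed=9))
        modified, pairs, truth = plant_ltr_elements(
            genome,
            LTRPlantSpec(n_elements=8, ltr_length_range=(150, 250),
                         internal_length_range=(100, 300), seed=10),
        )
        by_id = {p.element_id: p for p in pairs}
        for row in truth.elements.itertuples():
            p = by_id[row.element_id]
            five = modified.seq[row.five_prime_start : row.five_prime_start + row.ltr_length]
            three = modified.seq[row.three_prime_start : row.three_prime_start + row.ltr_length]
            assert five == p.five_prime.seq
            assert three == p.three_prime.seq
        assert len(modified.seq) == truth.genome_size_bp

    def test_too_many_elements_errors(self):
        genome = SequenceRecord("g", "ACGT")
        with pytest.raises(ValueError, match="larger genome"):
            plant_ltr_elements(genome, LTRPlantSpec(n_elements=10, seed=1))

    def test_determinism(self):
        genome, _ = generate_genome(GenomeSpec(length=30_000, seed=9))
        spec = LTRPlantSpec(n_elements=4, ltr_length_range=(100, 200),
                            internal_length_range=(100, 200), seed=11)
        m1, p1, _ = plant_ltr_elements(genome, spec)
        m2, p2, _ = plant_ltr_elements(genome, spec)
        assert m1.seq == m2.seq
        assert all(a.five_prime.seq == b.five_prime.seq for a, b in zip(p1, p2))


class TestPlantGenes:
    def test_single_exon_law_no_introns(self):
        genome, _ = generate_genome(GenomeSpec(length=200_000, seed=12))
        _, models, _ = plant_gene_models(
            genome, GeneSetSpec(n_genes=50, exon_count_mean=1.0, seed=13)
        )
        assert all(len(m.exons) == 1 for m in models)
        assert all(not derive_introns(m) for m in models)

    def test_genes_non_overlapping(self):
        genome, _ = generate_genome(GenomeSpec(length=400_000, seed=14))
        _, models, _ = plant_gene_models(genome, GeneSetSpec(n_genes=100, seed=15))
        spans = sorted(m.span for m in models)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_exon_gc_planted(self):
        genome, _ = generate_genome(
            GenomeSpec(length=600_000, gc_components=((0.5, 1.0),), seed=16)
        )
        modified, models, _ = plant_gene_models(
            genome, GeneSetSpec(n_genes=150, seed=17)
        )
        ex = "".join(
            modified.seq[s:e] for m in models for s, e in m.exons
        )
        codes = encode(ex)
        gc = np.mean((codes == 1) | (codes == 2))
        assert abs(gc - 0.4274) < 0.01

    def test_determinism(self):
        genome, _ = generate_genome(GenomeSpec(length=100_000, seed=18))
        spec = GeneSetSpec(n_genes=20, seed=19)
        m1, g1, _ = plant_gene_models(genome, spec)
        m2, g2, _ = plant_gene_models(genome, spec)
        assert m1.seq == m2.seq
        assert g1 == g2


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        genome, _ = generate_genome(GenomeSpec(length=10_000, seed=20))
        reads = simulate_reads(genome, ReadSimSpec(depth=10, read_length=100, seed=21))
        assert len(reads) == 1000

    def test_error_free_reads_are_substrings(self):
        genome, _ = generate_genome(GenomeSpec(length=5_000, seed=22))
        reads = simulate_reads(genome, ReadSimSpec(depth=2, read_length=80, seed=23))
        rc = revcomp(genome.seq)
        for r in reads[:50]:
            assert r.seq in genome.seq or r.seq in rc

    def test_mean_coverage_near_depth(self):
        genome, _ = generate_genome(GenomeSpec(length=20_000, seed=24))
        depths = []
        for seed in range(10):
            reads = simulate_reads(
                genome, ReadSimSpec(depth=8, read_length=100, seed=30 + seed)
            )
            depths.append(sum(len(r.seq) for r in reads) / 20_000)
        assert abs(np.mean(depths) - 8) / 8 < 0.05

    def test_read_longer_than_genome_errors(self):
        genome = SequenceRecord("g", "ACGTACGT")
        with pytest.raises(ValueError):
            simulate_reads(genome, ReadSimSpec(depth=1, read_length=100, seed=1))

    def test_error_rate_introduces_mismatches(self):
        genome, _ = generate_genome(GenomeSpec(length=5_000, seed=25))
        reads = simulate_reads(
            genome, ReadSimSpec(depth=5, read_length=80, error_rate=0.1, seed=26)
        )
        n_exact = sum(
            1 for r in reads if r.seq in genome.seq or r.seq in revcomp(genome.seq)
        )
        assert n_exact < len(reads) * 0.1  # P(no error in 80 bp) ~ 0.02%


def _tiny_gene_set(n=50, seed=40):
    genome, _ = generate_genome(GenomeSpec(length=400_000, seed=seed))
    _, models, _ = plant_gene_models(genome, GeneSetSpec(n_genes=n, seed=seed + 1))
    return models


def _models_with_introns(n, seed):
    """Cheap two-exon models with log-normal intron lengths (no genome)."""
    from neemkit import GeneModel

    rng = np.random.default_rng(seed)
    models = []
    pos = 0
    for i in range(n):
        e1, e2 = rng.integers(50, 400, size=2)
        intron = int(np.rint(rng.lognormal(5.5, 1.0))) + 1
        models.append(
            GeneModel(
                f"gene{i:05d}", "s", "+",
                ((pos, pos + e1), (pos + e1 + intron, pos + e1 + intron + e2)),
            )
        )
        pos += e1 + intron + e2 + 10
    return models


class TestSimulateExpression:
    def test_ef1a_present_positive_everywhere(self):
        models = _tiny_gene_set(50)
        table = simulate_expression(models, ExpressionSimSpec(seed=41))
        assert table.ef1a_id == "EF1A"
        assert (table.fpkm.loc["EF1A"] > 0).all()
        assert table.shape == (51, 4)

    def test_ef1a_collision_errors(self):
        models = _tiny_gene_set(10)
        with pytest.raises(ValueError, match="collides"):
            simulate_expression(
                models, ExpressionSimSpec(ef1a_id=models[0].gene_id, seed=42)
            )

    def test_zero_coupling_uncorrelated(self):
        models = _models_with_introns(2000, seed=43)
        table = simulate_expression(
            models, ExpressionSimSpec(structure_coupling=0.0, seed=44)
        )
        intron = [sum(e - s for s, e in derive_introns(m)) for m in models]
        fpkm = table.fpkm.loc[[m.gene_id for m in models], "leaf"]
        rho, _ = spearmanr(fpkm, intron)
        assert abs(rho) < 0.1

    def test_strong_coupling_detected(self):
        models = _models_with_introns(2000, seed=45)
        table = simulate_expression(
            models, ExpressionSimSpec(structure_coupling=0.8, seed=46)
        )
        intron = [sum(e - s for s, e in derive_introns(m)) for m in models]
        fpkm = table.fpkm.loc[[m.gene_id for m in models], "leaf"]
        rho, _ = spearmanr(fpkm, intron)
        assert rho >= 0.5

    def test_determinism(self):
        models = _tiny_gene_set(30)
        spec = ExpressionSimSpec(seed=47)
        t1 = simulate_expression(models, spec)
        t2 = simulate_expression(models, spec)
        assert t1.fpkm.equals(t2.fpkm)
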