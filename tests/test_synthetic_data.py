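"""Simulator correctness: retrohoming, population truth, reads, pileups."""

import math

import numpy as np
import pytest

from dgrscope.diversity_stats import pi
from dgrscope.synthetic_data import (
    SimulationConfig,
    make_vr_truth,
    random_tr,
    simulate_genome,
    simulate_pileup,
    simulate_population,
    simulate_reads,
    simulate_retrohoming,
)


class TestSimulateRetrohoming:
    def test_p_zero_is_identity(self, rng):
        tr = random_tr(80, 0.3, rng)
        assert simulate_retrohoming(tr, 0.0, rng) == tr

    def test_no_adenines_nothing_to_mutate(self, rng):
        assert simulate_retrohoming("CCCC", 1.0, rng) == "CCCC"

    def test_non_A_positions_always_verbatim(self, rng):
        tr = random_tr(60, 0.4, rng)
        for _ in range(100):
            out = simulate_retrohoming(tr, 1.0, rng)
            for t, o in zip(tr, out):
                if t != "A":
                    assert o == t

    def test_changed_fraction_matches_binomial_expectation(self, rng):
        """At p=1 each adenine changes with probability 3/4; the mean
        changed fraction over 10,000 replicates sits within 3 SE of it."""
        tr = "A" * 20
        k, reps, q = 20, 10_000, 0.75
        changed = sum(
            sum(b != "A" for b in simulate_retrohoming(tr, 1.0, rng))
            for _ in range(reps)
        )
        frac = changed / (k * reps)
        se = math.sqrt(q * (1 - q) / (k * reps))
        assert abs(frac - q) <= 3 * se


class TestSimulateGenomeAndPopulation:
    def test_layout_invariants(self, small_sim):
        _, genome, loci, _ = small_sim
        contig = next(iter(genome))
        for locus in loci:
            assert locus.completeness == "complete"
            tr_seq = locus.tr.fetch(genome, oriented=True)
            for tgt, _, vr in locus.iter_vrs():
                assert tgt.cds.contains(vr)
                assert vr.fetch(genome) == tr_seq  # VR planted as TR copy

    def test_truth_haplotype_frequencies_sum_to_one(self, small_sim):
        _, _, _, truth = small_sim
        for v in truth.vrs.values():
            assert sum(f for _, f in v.haplotypes) == pytest.approx(1.0)
            assert v.diversified

    def test_d_zero_plants_nothing(self, rng):
        cfg = SimulationConfig(seed=2, genome_length=12_000, n_loci=2,
                               diversified_cell_fraction=0.0)
        genome, loci = simulate_genome(cfg, rng)
        truth = simulate_population(genome, loci, cfg, rng)
        for v in truth.vrs.values():
            assert not v.diversified
            assert v.haplotypes == [(v.ref_seq, 1.0)]
            assert v.expected_nonref == 0.0

    @pytest.mark.parametrize("d, p", [(1.0, 1.0), (0.5, 0.5)])
    def test_expected_nonref_closed_form(self, d, p, rng):
        truth = make_vr_truth(random_tr(100, 0.25, rng), d, p, 200, rng)
        assert truth.expected_nonref == pytest.approx(d * p * 0.75)

    def test_genome_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(SimulationConfig(genome_length=1_000, n_loci=3), rng)


class TestSimulatePileup:
    def test_null_with_no_error_is_monomorphic(self, rng):
        truth = make_vr_truth(random_tr(100, 0.25, rng), 0.0, 0.5, 100, rng)
        for pc in simulate_pileup(truth, 50, 0.0, rng):
            assert pi(pc) == 0.0

    def test_observed_nonref_tracks_expectation(self, rng):
        """d=1, p=1: expected non-reference fraction 0.75 at adenine
        positions, recovered within 3 binomial SE at high coverage."""
        truth = make_vr_truth("A" * 200, 1.0, 1.0, 2_000, rng)
        pile = simulate_pileup(truth, 1000, 0.0, rng)
        nonref = sum(pc.depth - pc.a for pc in pile)
        total = sum(pc.depth for pc in pile)
        se = math.sqrt(0.75 * 0.25 / total)
        assert abs(nonref / total - 0.75) <= 3 * se

    def test_pi_at_fully_diversified_position(self, rng):
        """At d=p=1 every adenine position is equiprobable over {A,C,G,T},
        so π = 1 − 4·(1/4)² = 0.75; observed per-position π concentrates
        there at high coverage (finite cells/reads shrink it slightly)."""
        truth = make_vr_truth("A" * 300, 1.0, 1.0, 5_000, rng)
        pile = simulate_pileup(truth, 2000, 0.0, rng)
        mean_pi = np.mean([pi(pc) for pc in pile])
        # population haplotype draw + multinomial sampling both shrink π
        # slightly below the infinite-population value
        assert mean_pi == pytest.approx(0.75, abs=0.02)

    def test_depth_is_poisson_around_coverage(self, rng):
        truth = make_vr_truth(random_tr(500, 0.25, rng), 0.0, 0.0, 10, rng)
        pile = simulate_pileup(truth, 40, 0.0, rng)
        depths = [pc.depth for pc in pile]
        se = math.sqrt(40 / len(depths))
        assert abs(np.mean(depths) - 40) <= 3 * se


class TestSimulateReads:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        digests = []
        for run in range(2):
            cfg = SimulationConfig(seed=9, genome_length=12_000, n_loci=2,
                                   n_cells=30, coverage=10)
            rng = np.random.default_rng(cfg.seed)
            genome, loci = simulate_genome(cfg, rng)
            truth = simulate_population(genome, loci, cfg, rng)
            prefix = tmp_path / f"run{run}"
            simulate_reads(genome, truth, cfg, rng,
                           fastq_prefix=str(prefix), sam_path=str(prefix) + ".sam")
            import hashlib

            h = hashlib.sha256()
            for suffix in ("_R1.fastq", "_R2.fastq", ".sam"):
                h.update((tmp_path / f"run{run}{suffix}").read_bytes())
            h.update(truth.to_json().encode())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_error_free_reference_population_is_monomorphic(self, rng, tmp_path):
        from dgrscope import pipeline

        cfg = SimulationConfig(seed=4, genome_length=12_000, n_loci=2,
                               n_cells=20, coverage=20,
                               diversified_cell_fraction=0.0, seq_error_rate=0.0)
        genome, loci = simulate_genome(cfg, rng)
        truth = simulate_population(genome, loci, cfg, rng)
        sam = tmp_path / "null.sam"
        simulate_reads(genome, truth, cfg, rng, sam_path=str(sam))
        pileups = pipeline.pileups_from_bam(str(sam), loci, genome)
        for pile in pileups.values():
            for pc in pile:
                if pc.depth:
                    assert pi(pc) == 0.0
                    assert pc.count(pc.ref_base) == pc.depth

    def test_error_rate_recovered_genome_wide(self, rng, tmp_path):
        cfg = SimulationConfig(seed=5, genome_length=12_000, n_loci=2,
                               n_cells=10, coverage=15,
                               diversified_cell_fraction=0.0, seq_error_rate=0.01)
        genome, loci = simulate_genome(cfg, rng)
        truth = simulate_population(genome, loci, cfg, rng)
        reads = simulate_reads(genome, truth, cfg, rng)
        contig = next(iter(genome))
        ref = genome[contig]
        mismatches = total = 0
        for r in reads:
            for pos, seq in ((r["pos1"], r["seq1"]), (r["pos2"], r["seq2"])):
                total += len(seq)
                mismatches += sum(
                    1 for i, b in enumerate(seq) if b != ref[pos + i])
        rate = mismatches / total
        se = math.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) <= 3 * se

    def test_mean_depth_near_requested_coverage(self, rng, tmp_path):
        cfg = SimulationConfig(seed=6, genome_length=12_000, n_loci=2,
                               n_cells=10, coverage=30,
                               diversified_cell_fraction=0.0, seq_error_rate=0.0)
        genome, loci = simulate_genome(cfg, rng)
        truth = simulate_population(genome, loci, cfg, rng)
        reads = simulate_reads(genome, truth, cfg, rng)
        glen = len(genome[next(iter(genome))])
        depth = np.zeros(glen)
        for r in reads:
            for pos, seq in ((r["pos1"], r["seq1"]), (r["pos2"], r["seq2"])):
                depth[pos : pos + len(seq)] += 1
        interior = depth[1000 : glen - 1000]
        assert abs(interior.mean() - cfg.coverage) / cfg.coverage <= 0.10
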