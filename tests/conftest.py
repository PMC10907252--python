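"""Shared fixtures: tiny hand-built genomes and loci, simulator instances."""

from __future__ import annotations

import numpy as np
import pytest

from dgrscope.repeat_model import DGRLocus, GenomicInterval, TargetGene
from dgrscope.synthetic_data import SimulationConfig, simulate_genome, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20240214)


@pytest.fixture
def toy_locus():
    """A plus-strand locus on a 400 bp contig with one target and one VR.

    Layout: TR at 20-50, CDS at 100-250 (frame 0), VR at 130-160; TR and
    VR sequences are identical except at TR adenine positions, where the
    VR carries planted substitutions.
    """
    rng = np.random.default_rng(7)
    bases = "ACGT"
    genome = list(rng.choice(list(bases), size=400))
    tr_seq = "GGATCAACGGTTACCGGATAACCGGTTACC"  # 30 bp, A at 2,5,6,12,17,19,20,27
    assert len(tr_seq) == 30
    vr_seq = list(tr_seq)
    vr_seq[5] = "G"   # planted change at a TR adenine
    vr_seq[19] = "C"  # planted change at a TR adenine
    genome[20:50] = tr_seq
    genome[130:160] = vr_seq
    genome_map = {"chr": "".join(genome)}
    tr = GenomicInterval("chr", 20, 50, "+")
    cds = GenomicInterval("chr", 100, 250, "+")
    vr = GenomicInterval("chr", 130, 160, "+")
    rt = GenomicInterval("chr", 300, 360, "+")
    acc = GenomicInterval("chr", 360, 390, "+")
    target = TargetGene(gene_id="g1", cds=cds, vrs=[vr])
    locus = DGRLocus(locus_id="L1", targets=[target], rt=rt, accessory=acc, tr=tr)
    return genome_map, locus, tr_seq, "".join(vr_seq)


@pytest.fixture
def small_sim(rng):
    """Small simulated genome: 2 complete loci, 50 cells, half diversified."""
    cfg = SimulationConfig(seed=11, genome_length=12_000, n_loci=2,
                           n_cells=50, coverage=30)
    genome, loci = simulate_genome(cfg, rng)
    truth = simulate_population(genome, loci, cfg, rng)
    return cfg, genome, loci, truth
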