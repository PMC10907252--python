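"""Synthetic genomes, mutagenic retrohoming, and sequencing-read simulation.

The generative model mirrors how DGR diversity arises in a clonal
aggregate: a reference population of identical cells, of which a fraction
``d`` has undergone mutagenic retrohoming — each adenine of the template
repeat independently replaced, with probability ``p``, by a uniformly
random nucleotide (so the per-adenine *change* probability is ``3p/4``).
Paired short reads with a uniform per-base error rate ``e`` are drawn from
this population, or, on the fast path, per-position base counts are drawn
directly from the population allele frequencies. Every simulation carries
a truth table so detection can be scored without external data.

Default condition: 100-cell aggregates, 100 bp VRs with 25% TR adenines,
50× coverage, 250 bp paired reads (500 ± 50 bp inserts), 1% sequencing
error — small enough to run anywhere, dense enough that a half-diversified
population is unambiguous at targeted positions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .diversity_stats import PositionCounts
from .repeat_model import DGRLocus, GenomicInterval, TargetGene

__all__ = [
    "SimulationConfig",
    "VRTruth",
    "TruthTable",
    "simulate_retrohoming",
    "random_tr",
    "simulate_genome",
    "simulate_population",
    "make_vr_truth",
    "simulate_pileup",
    "simulate_reads",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimulationConfig:
    """All knobs of the simulator; reproducible given ``seed``."""

    seed: int = 0
    genome_length: int = 20_000
    n_loci: int = 3
    vr_length: int = 100
    tr_adenine_fraction: float = 0.25
    per_A_substitution_prob: float = 0.5
    diversified_cell_fraction: float = 0.5
    n_cells: int = 100
    coverage: float = 50.0
    read_length: int = 250
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    seq_error_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("tr_adenine_fraction", "per_A_substitution_prob",
                     "diversified_cell_fraction", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.genome_length, self.vr_length, self.read_length, self.n_cells) <= 0:
            raise ValueError("lengths and cell counts must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def random_tr(length: int, adenine_fraction: float, rng: np.random.Generator) -> str:
    """Random template repeat with the requested expected adenine fraction."""
    q = (1.0 - adenine_fraction) / 3.0
    return "".join(rng.choice(list(BASES), size=length,
                              p=[adenine_fraction, q, q, q]))


def simulate_retrohoming(tr_seq: str, p: float, rng: np.random.Generator) -> str:
    """One mutagenic retrohoming event applied to a template repeat.

    Each adenine independently, with probability ``p``, is replaced by a
    base drawn uniformly from {A,C,G,T}; all other positions are copied
    verbatim. Replacement may redraw the adenine itself, so the expected
    fraction of *changed* adenines is ``3p/4``.
    """
    out = list(tr_seq)
    for i, b in enumerate(tr_seq):
        if b == "A" and rng.random() < p:
            out[i] = BASES[rng.integers(4)]
    return "".join(out)


@dataclass
class VRTruth:
    """Ground truth for one simulated VR."""

    vr_id: str
    contig: str
    start: int  # genome coords of the VR, half-open
    end: int
    ref_seq: str  # undiversified VR (= TR copy) on the plus strand
    a_offsets: list[int]  # offsets within the VR aligned to TR adenines
    diversified: bool
    expected_nonref: float  # at A-targeted positions; 0 elsewhere
    haplotypes: list[tuple[str, float]] = field(default_factory=list)

    @property
    def a_positions(self) -> list[int]:
        return [self.start + o for o in self.a_offsets]


@dataclass
class TruthTable:
    """Per-VR truth records plus the config that generated them."""

    vrs: dict[str, VRTruth]
    config: SimulationConfig

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "vrs": {
                k: {
                    "contig": v.contig, "start": v.start, "end": v.end,
                    "ref_seq": v.ref_seq, "a_offsets": v.a_offsets,
                    "diversified": v.diversified,
                    "expected_nonref": v.expected_nonref,
                    "haplotypes": [[h, f] for h, f in v.haplotypes],
                }
                for k, v in self.vrs.items()
            },
        }
        return json.dumps(payload, indent=2)


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[DGRLocus]]:
    """Random genome carrying ``cfg.n_loci`` complete DGR loci.

    Each locus is laid out on the plus strand as RT — accessory — TR —
    target CDS, with a single VR inside the CDS that starts as an exact
    copy of the TR (codon-aligned). Inter-feature spacing leaves room for
    read pairs anchored in unique flanking sequence.
    """
    L = cfg.vr_length
    rt_len, acc_len, spacer = 300, 150, 150
    cds_pad = 51  # codon-aligned padding on each side of the VR
    cds_len = cds_pad + L + cds_pad
    cds_len += (-cds_len) % 3
    locus_span = rt_len + acc_len + L + cds_len + 5 * spacer
    if cfg.genome_length < cfg.n_loci * locus_span + spacer:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for "
            f"{cfg.n_loci} loci (need ≥ {cfg.n_loci * locus_span + spacer})"
        )
    genome = list(rng.choice(list(BASES), size=cfg.genome_length))
    contig = "sim_contig"
    loci = []
    stride = cfg.genome_length // cfg.n_loci
    for k in range(cfg.n_loci):
        base = k * stride + spacer
        rt = GenomicInterval(contig, base, base + rt_len)
        acc = GenomicInterval(contig, rt.end + spacer, rt.end + spacer + acc_len)
        tr = GenomicInterval(contig, acc.end + spacer, acc.end + spacer + L)
        cds_start = tr.end + spacer
        cds = GenomicInterval(contig, cds_start, cds_start + cds_len)
        vr_start = cds_start + cds_pad
        vr = GenomicInterval(contig, vr_start, vr_start + L)
        tr_seq = random_tr(L, cfg.tr_adenine_fraction, rng)
        genome[tr.start : tr.end] = tr_seq
        genome[vr.start : vr.end] = tr_seq  # VR starts as an exact TR copy
        target = TargetGene(gene_id=f"locus{k + 1}_t1", cds=cds, vrs=[vr])
        loci.append(DGRLocus(locus_id=f"locus{k + 1}", targets=[target],
                             rt=rt, accessory=acc, tr=tr))
    return {contig: "".join(genome)}, loci


def simulate_population(
    genome: Mapping[str, str],
    loci: Sequence[DGRLocus],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> TruthTable:
    """Clonal population with a diversified-cell fraction.

    ``round(d · n_cells)`` cells carry VRs independently rewritten by
    :func:`simulate_retrohoming`; the remainder carry the reference. The
    truth table records per-VR haplotype frequencies and the expected
    non-reference fraction ``d · p · 3/4`` at adenine-targeted positions.
    """
    d = cfg.diversified_cell_fraction
    p = cfg.per_A_substitution_prob
    n_div = round(d * cfg.n_cells)
    if d > 0 and n_div < 1:
        raise ValueError("diversified_cell_fraction too small for n_cells")
    expected = d * p * 0.75
    vrs: dict[str, VRTruth] = {}
    for locus in loci:
        tr_seq = locus.tr.fetch(genome, oriented=True) if locus.tr else None
        for tgt, i, vr in locus.iter_vrs():
            vr_id = f"{tgt.gene_id}:VR{i + 1}"
            ref_seq = vr.fetch(genome)
            donor = tr_seq if tr_seq is not None else ref_seq
            a_offsets = [j for j, b in enumerate(donor) if b == "A"]
            hap_counts: dict[str, int] = {}
            n_ref = cfg.n_cells - n_div
            if n_ref:
                hap_counts[ref_seq] = n_ref
            for _ in range(n_div):
                h = simulate_retrohoming(donor, p, rng)
                hap_counts[h] = hap_counts.get(h, 0) + 1
            vrs[vr_id] = VRTruth(
                vr_id=vr_id, contig=vr.contig, start=vr.start, end=vr.end,
                ref_seq=ref_seq, a_offsets=a_offsets,
                diversified=bool(n_div and p > 0 and a_offsets),
                expected_nonref=expected,
                haplotypes=[(h, c / cfg.n_cells) for h, c in sorted(hap_counts.items())],
            )
    return TruthTable(vrs=vrs, config=cfg)


def make_vr_truth(
    tr_seq: str,
    d: float,
    p: float,
    n_cells: int,
    rng: np.random.Generator,
    vr_id: str = "vr",
    contig: str = "sim_contig",
    start: int = 0,
) -> VRTruth:
    """Truth record for a single free-standing VR (no genome needed).

    The VR reference is the TR copy itself; ``round(d · n_cells)`` cells
    carry independently retrohomed haplotypes. This is the unit the
    classifier-calibration harnesses are built from.
    """
    n_div = round(d * n_cells)
    a_offsets = [j for j, b in enumerate(tr_seq) if b == "A"]
    hap_counts: dict[str, int] = {}
    if n_cells - n_div:
        hap_counts[tr_seq] = n_cells - n_div
    for _ in range(n_div):
        h = simulate_retrohoming(tr_seq, p, rng)
        hap_counts[h] = hap_counts.get(h, 0) + 1
    return VRTruth(
        vr_id=vr_id, contig=contig, start=start, end=start + len(tr_seq),
        ref_seq=tr_seq, a_offsets=a_offsets,
        diversified=bool(n_div and p > 0 and a_offsets),
        expected_nonref=d * p * 0.75,
        haplotypes=[(h, c / n_cells) for h, c in sorted(hap_counts.items())],
    )


def _error_mixed_probs(p_true: np.ndarray, e: float) -> np.ndarray:
    """Observed base probabilities after uniform sequencing error ``e``."""
    return p_true * (1.0 - e) + (e / 3.0) * (1.0 - p_true)


def simulate_pileup(
    truth: VRTruth,
    coverage: float,
    e: float,
    rng: np.random.Generator,
) -> list[PositionCounts]:
    """Fast-path pileup for one VR, bypassing read simulation.

    Depth at each position is Poisson(coverage); base counts are
    multinomial around the population allele frequencies implied by the
    truth haplotypes, mixed with a uniform error ``e``. Statistically
    equivalent to piling up ideal reads at uniform coverage.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = truth.end - truth.start
    freqs = np.zeros((L, 4))
    if truth.haplotypes:
        for hap, f in truth.haplotypes:
            for j, b in enumerate(hap):
                freqs[j, _BASE_INDEX[b]] += f
    else:  # no explicit haplotypes: use the closed-form expectation
        for j, b in enumerate(truth.ref_seq):
            freqs[j, _BASE_INDEX[b]] = 1.0
        q = truth.expected_nonref
        for off in truth.a_offsets:
            ref_i = _BASE_INDEX[truth.ref_seq[off]]
            freqs[off] = q / 3.0
            freqs[off, ref_i] = 1.0 - q
    depths = rng.poisson(coverage, size=L)
    out = []
    for j in range(L):
        probs = _error_mixed_probs(freqs[j], e)
        probs = probs / probs.sum()
        n_a, n_c, n_g, n_t = rng.multinomial(depths[j], probs)
        out.append(PositionCounts(
            genome_pos=truth.start + j, ref_base=truth.ref_seq[j],
            a=int(n_a), c=int(n_c), g=int(n_g), t=int(n_t),
            contig=truth.contig,
        ))
    return out


def _apply_errors(seq: str, e: float, rng: np.random.Generator) -> str:
    if e <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < e)
    for i in hits:
        alts = [b for b in BASES if b != out[i]]
        out[i] = alts[rng.integers(3)]
    return "".join(out)


def simulate_reads(
    genome: Mapping[str, str],
    truth: TruthTable,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    fastq_prefix: str | None = None,
    sam_path: str | None = None,
) -> list[dict]:
    """Paired short reads from the simulated population, with ideal alignments.

    Fragments are sampled uniformly along the genome from cells drawn in
    proportion to haplotype frequency; each base suffers a uniform,
    independent substitution error ``cfg.seq_error_rate``. Because
    haplotypes differ from the reference only by substitutions, the true
    alignment of every read is known by construction and is emitted as a
    coordinate-sorted SAM (via pysam) when ``sam_path`` is given, so no
    external mapper is needed downstream. FASTQ mates are written 5'->3'
    (mate 2 reverse-complemented) when ``fastq_prefix`` is given.

    Returns the reads as dicts (name, contig, pos1/pos2, seq1/seq2 in
    reference orientation).
    """
    contig = next(iter(genome))
    ref = genome[contig]
    glen = len(ref)
    L = cfg.read_length
    n_frags = max(1, int(round(cfg.coverage * glen / (2 * L))))

    # assign each cell a haplotype per VR, consistent with truth frequencies
    vr_list = list(truth.vrs.values())
    cell_haps: list[dict[str, str]] = [dict() for _ in range(cfg.n_cells)]
    for v in vr_list:
        pool: list[str] = []
        for hap, f in v.haplotypes:
            pool.extend([hap] * round(f * cfg.n_cells))
        while len(pool) < cfg.n_cells:
            pool.append(v.ref_seq)
        rng.shuffle(pool)
        for c in range(cfg.n_cells):
            cell_haps[c][v.vr_id] = pool[c]

    reads = []
    for n in range(n_frags):
        insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = max(L, min(insert, glen))
        start = int(rng.integers(0, glen - insert + 1))
        cell = int(rng.integers(cfg.n_cells))
        frag = list(ref[start : start + insert])
        for v in vr_list:
            lo, hi = max(start, v.start), min(start + insert, v.end)
            if lo < hi:
                hap = cell_haps[cell][v.vr_id]
                for g in range(lo, hi):
                    frag[g - start] = hap[g - v.start]
        frag_seq = "".join(frag)
        seq1 = _apply_errors(frag_seq[:L], cfg.seq_error_rate, rng)
        seq2 = _apply_errors(frag_seq[-L:], cfg.seq_error_rate, rng)
        reads.append({
            "name": f"sim_{n:07d}", "contig": contig,
            "pos1": start, "seq1": seq1,
            "pos2": start + insert - L, "seq2": seq2,
        })

    if fastq_prefix is not None:
        with open(f"{fastq_prefix}_R1.fastq", "w") as f1, \
                open(f"{fastq_prefix}_R2.fastq", "w") as f2:
            for r in reads:
                q = "I" * L
                f1.write(f"@{r['name']}/1\n{r['seq1']}\n+\n{q}\n")
                r2 = str(Seq(r["seq2"]).reverse_complement())
                f2.write(f"@{r['name']}/2\n{r2}\n+\n{q}\n")
    if sam_path is not None:
        write_ideal_sam(reads, {contig: glen}, sam_path, L)
    return reads


def write_ideal_sam(reads: Sequence[dict], contig_lengths: Mapping[str, int],
                    path: str, read_length: int) -> None:
    """Write the known-by-construction alignments as coordinate-sorted SAM."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()],
    }
    records = []
    for r in reads:
        for mate, (flag, pos, seq, mpos) in enumerate([
            (0x1 | 0x2 | 0x20 | 0x40, r["pos1"], r["seq1"], r["pos2"]),
            (0x1 | 0x2 | 0x10 | 0x80, r["pos2"], r["seq2"], r["pos1"]),
        ]):
            records.append((pos, r["name"], flag, seq, mpos))
    records.sort(key=lambda x: (x[0], x[1]))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for pos, name, flag, seq, mpos in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.next_reference_id = 0
            a.next_reference_start = mpos
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.template_length = 0
            out.write(a)
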