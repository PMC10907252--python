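"""End-to-end validation harnesses: classifier calibration, power,
combinatorics and trans-matching checks against planted truth.

Each harness simulates its own inputs from a supplied RNG, runs the
ordinary pipeline code paths, and scores the result against the
simulation's truth table. They exist so that the package's operating
characteristics — false-positive rate of the 2-sd rule under a null,
detection power at a stated effect size, exactness of the sequence-space
formula, donor-classification accuracy — are measurable quantities, not
assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .diversity_stats import (
    ProfileConfig,
    aggregate_calls,
    call_diversified,
    profile_region,
)
from .repeat_model import DGRLocus, GenomicInterval, TargetGene
from .sequence_space import codon_outcomes, translate_codon, vr_polypeptide_count
from .synthetic_data import (
    make_vr_truth,
    random_tr,
    simulate_pileup,
    simulate_retrohoming,
)
from .trans_matcher import classify_locus_mode, match_vr_to_trs

__all__ = [
    "OperatingPoint",
    "classifier_operating_point",
    "enumerate_peptides",
    "combinatorics_oracle_agreement",
    "trans_mode_recovery",
    "retrohoming_change_fraction",
    "null_nonref_rate",
]

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")


@dataclass
class OperatingPoint:
    """Classifier behaviour over many simulated aggregates."""

    fraction_called: float  # of VRs with a present call
    locus_recovery: float   # fraction of (simulated) loci with >=1 true VR
    n_calls_present: int
    n_calls_total: int


def classifier_operating_point(
    rng: np.random.Generator,
    n_aggregates: int = 100,
    vrs_per_aggregate: int = 20,
    d: float = 0.0,
    p: float = 0.5,
    coverage: float = 50.0,
    error_rate: float = 0.01,
    vr_length: int = 100,
    a_fraction: float = 0.25,
    n_cells: int = 100,
    vrs_per_locus: int = 4,
    metric: str = "pi",
    cfg: ProfileConfig = ProfileConfig(),
) -> OperatingPoint:
    """Fraction of VRs called diversified over simulated aggregates.

    With ``d=0`` this measures the false-positive rate of the 2-sd rule
    against sequencing error alone; with ``d>0`` it measures detection
    power at per-position effect size ``d·p·3/4``. VRs are grouped
    ``vrs_per_locus`` at a time into synthetic loci to score locus-level
    aggregation (a locus is recovered when at least one VR is called).
    """
    n_called = n_present = n_total = 0
    loci_recovered = loci_total = 0
    for _ in range(n_aggregates):
        locus_calls = []
        for v in range(vrs_per_aggregate):
            tr = random_tr(vr_length, a_fraction, rng)
            truth = make_vr_truth(tr, d, p, n_cells, rng)
            pile = simulate_pileup(truth, coverage, error_rate, rng)
            prof = profile_region(pile, truth.a_positions, cfg)
            call = call_diversified(prof, metric, cfg)
            n_total += 1
            if call.present:
                n_present += 1
                n_called += bool(call.diversified)
            locus_calls.append(call)
            if (v + 1) % vrs_per_locus == 0:
                loci_total += 1
                loci_recovered += aggregate_calls(locus_calls) is True
                locus_calls = []
    return OperatingPoint(
        fraction_called=n_called / max(n_present, 1),
        locus_recovery=loci_recovered / max(loci_total, 1),
        n_calls_present=n_present,
        n_calls_total=n_total,
    )


def enumerate_peptides(codons_with_offsets) -> set[str]:
    """Brute-force oracle: distinct stop-free peptides over the full
    nucleotide outcome space of a VR's codons.

    Enumerates every joint substitution at the targeted offsets,
    translates each full variant, and deduplicates — sharing no algebra
    with the per-codon product formula it checks.
    """
    variant_sets = []
    for ref, offsets in codons_with_offsets:
        variants = set()
        for combo in product(BASES, repeat=len(offsets)):
            codon = list(ref)
            for off, b in zip(sorted(offsets), combo):
                codon[off] = b
            variants.add("".join(codon))
        variant_sets.append(sorted(variants))
    peptides = set()
    for combo in product(*variant_sets):
        aas = [translate_codon(c) for c in combo]
        if None not in aas:
            peptides.add("".join(aas))
    return peptides


def random_vr_codon_spec(rng: np.random.Generator, max_targeted: int = 6):
    """Random VR description: 1-3 non-stop codons with ≤ ``max_targeted``
    targeted offsets in total."""
    n_codons = int(rng.integers(1, 4))
    spec = []
    budget = max_targeted
    for _ in range(n_codons):
        while True:
            ref = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
            if ref not in STOPS:
                break
        k = int(rng.integers(0, min(3, budget) + 1))
        offsets = frozenset(rng.choice(3, size=k, replace=False).tolist())
        budget -= len(offsets)
        spec.append((ref, offsets))
    return spec


def combinatorics_oracle_agreement(rng: np.random.Generator,
                                   n_vrs: int = 500) -> float:
    """Fraction of random VRs where the exact product formula equals the
    brute-force peptide enumeration (should be 1.0)."""
    agree = 0
    for _ in range(n_vrs):
        spec = random_vr_codon_spec(rng)
        spaces = [codon_outcomes(ref, offs, i) for i, (ref, offs) in enumerate(spec)]
        agree += vr_polypeptide_count(spaces) == len(enumerate_peptides(spec))
    return agree / n_vrs


def _stub_locus(locus_id: str, length: int, with_tr: bool) -> DGRLocus:
    iv = GenomicInterval("c", 0, length, "+")
    tgt = TargetGene(gene_id=f"{locus_id}_t", cds=iv,
                     vrs=[GenomicInterval("c", 0, length, "+")])
    return DGRLocus(locus_id=locus_id, targets=[tgt], tr=iv if with_tr else None)


def trans_mode_recovery(rng: np.random.Generator, n_genomes: int = 100,
                        min_tr_length: int = 40) -> float:
    """Fraction of random genomes whose cis / trans / orphan construction
    is classified exactly.

    Each genome carries a complete locus A (VR retrohomed from its own
    TR), a TR-less locus B whose VR was written by A's TR acting in
    trans, and a locus C whose VR matches no TR in the genome. Donor TRs
    are i.i.d. random sequences of ≥ ``min_tr_length`` bp, so chance
    compatibility with a non-donor is negligible.
    """
    correct = 0
    for _ in range(n_genomes):
        length = int(rng.integers(min_tr_length, min_tr_length + 21))
        tr_a = random_tr(length, 0.3, rng)
        tr_c = random_tr(length, 0.3, rng)
        all_trs = [("A", tr_a), ("C", tr_c)]
        vr_a = simulate_retrohoming(tr_a, float(rng.random()), rng)
        vr_b = simulate_retrohoming(tr_a, float(rng.random()), rng)
        vr_orphan = random_tr(length, 0.3, rng)

        ok = True
        for locus, vr_seq, expected in [
            (_stub_locus("A", length, True), vr_a, "cis"),
            (_stub_locus("B", length, False), vr_b, "trans"),
            (_stub_locus("C", length, True), vr_orphan, "orphan"),
        ]:
            matches = {"v": match_vr_to_trs(vr_seq, all_trs, vr_id="v")}
            mode = classify_locus_mode(locus, matches)["v"]
            ok &= mode == expected
            donor_ok = {m.donor_tr_locus: m.compatible for m in matches["v"]}
            if expected in ("cis", "trans"):
                ok &= donor_ok["A"] and not donor_ok["C"]
            else:
                ok &= not donor_ok["A"] and not donor_ok["C"]
        correct += ok
    return correct / n_genomes


def retrohoming_change_fraction(rng: np.random.Generator, p: float = 0.5,
                                n_adenines: int = 20,
                                replicates: int = 10_000) -> dict:
    """Observed fraction of adenines changed by retrohoming vs the
    binomial expectation 3p/4, with its standard error."""
    tr = "A" * n_adenines
    changed = sum(
        sum(b != "A" for b in simulate_retrohoming(tr, p, rng))
        for _ in range(replicates)
    )
    n = n_adenines * replicates
    expected = 0.75 * p
    return {
        "observed": changed / n,
        "expected": expected,
        "se": math.sqrt(expected * (1 - expected) / n),
    }


def null_nonref_rate(rng: np.random.Generator, error_rate: float = 0.01,
                     n_positions: int = 20_000, coverage: float = 30.0) -> dict:
    """Genome-wide non-reference read fraction on null data (no
    retrohoming): should equal the sequencing error rate."""
    truth = make_vr_truth(random_tr(n_positions, 0.25, rng), 0.0, 0.0, 10, rng)
    pile = simulate_pileup(truth, coverage, error_rate, rng)
    nonref = sum(pc.depth - pc.count(pc.ref_base) for pc in pile)
    total = sum(pc.depth for pc in pile)
    return {
        "observed": nonref / total,
        "expected": error_rate,
        "se": math.sqrt(error_rate * (1 - error_rate) / total),
    }
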