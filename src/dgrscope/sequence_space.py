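"""Exact combinatorics of the protein sequence space reachable by DGR mutagenesis.

Each adenine-targeted position in a variable repeat can, after mutagenic
retrohoming, carry any of the four nucleotides. A codon with k targeted
offsets therefore reaches exactly 4^k nucleotide variants; the number of
distinct polypeptides of a VR is the product over its codons of the number
of distinct non-stop amino acids those variants translate to (codons vary
independently, so per-codon counts multiply). Totals routinely exceed
10^200, so all counting uses exact integer arithmetic; floats appear only
in the human-readable scientific rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .repeat_model import DGRLocus, GenomicInterval, TargetGene, VariablePosition

__all__ = [
    "CodonSpace",
    "SequenceSpaceReport",
    "codon_outcomes",
    "vr_polypeptide_count",
    "target_polypeptide_count",
    "genome_total",
    "nonsense_report",
    "sci_notation",
    "build_report",
]

BASES = "ACGT"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str | None:
    """Amino acid for an internal codon under the standard genetic code.

    Returns ``None`` for a stop codon.
    """
    if codon in STOP_CODONS:
        return None
    return _CODON_TO_AA[codon]


@dataclass
class CodonSpace:
    """The outcome space of one codon under adenine-targeted mutagenesis."""

    codon_index: int
    ref_codon: str
    targeted_offsets: frozenset[int]
    reachable_codons: frozenset[str]
    reachable_aa: frozenset[str]
    stop_reachable: bool

    @property
    def n_aa(self) -> int:
        return len(self.reachable_aa)


def codon_outcomes(ref_codon: str, targeted_offsets: Iterable[int],
                   codon_index: int = 0) -> CodonSpace:
    """Exhaustively enumerate the codons reachable by substituting the
    targeted offsets, and their translations.

    The reference nucleotide is itself a possible outcome ("random
    nucleotides" includes the original adenine), so the reference codon is
    always reachable and |reachable_codons| = 4^k exactly.
    """
    ref_codon = ref_codon.upper()
    if len(ref_codon) != 3 or any(b not in BASES for b in ref_codon):
        raise ValueError(f"invalid codon {ref_codon!r} (ambiguity codes not allowed)")
    offsets = frozenset(targeted_offsets)
    if not offsets <= {0, 1, 2}:
        raise ValueError(f"targeted offsets must be within {{0,1,2}}, got {sorted(offsets)}")

    reachable = set()
    for combo in product(BASES, repeat=len(offsets)):
        codon = list(ref_codon)
        for off, base in zip(sorted(offsets), combo):
            codon[off] = base
        reachable.add("".join(codon))
    aa = {translate_codon(c) for c in reachable}
    stop_reachable = None in aa
    aa.discard(None)
    if not aa:
        # impossible when ref_codon is not itself a stop codon
        raise ValueError(f"all outcomes of {ref_codon} are stop codons")
    return CodonSpace(
        codon_index=codon_index,
        ref_codon=ref_codon,
        targeted_offsets=offsets,
        reachable_codons=frozenset(reachable),
        reachable_aa=frozenset(aa),  # type: ignore[arg-type]
        stop_reachable=stop_reachable,
    )


def vr_polypeptide_count(codon_spaces: Sequence[CodonSpace]) -> int:
    """Distinct polypeptides reachable for one VR: product of per-codon
    amino-acid outcome counts (exact integer)."""
    if not codon_spaces:
        raise ValueError("VR has no targeted codons")
    indices = [c.codon_index for c in codon_spaces]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate codon indices in VR")
    return math.prod(c.n_aa for c in codon_spaces)


def vr_nucleotide_count(codon_spaces: Sequence[CodonSpace]) -> int:
    """Distinct nucleotide sequences reachable for one VR: 4^(total targeted)."""
    return math.prod(len(c.reachable_codons) for c in codon_spaces)


def target_polypeptide_count(per_vr: Mapping[str, int]) -> int:
    """Product of a target's per-VR polypeptide counts."""
    if not per_vr:
        raise ValueError("target has no VRs")
    return math.prod(per_vr.values())


def genome_total(per_target: Mapping[str, int]) -> int:
    """Product of per-target counts: the genome's total protein sequence space."""
    if not per_target:
        raise ValueError("no targets supplied")
    return math.prod(per_target.values())


def sci_notation(n: int, sig: int = 2) -> str:
    """Render an exact integer as e.g. ``1.5 × 10^294`` (``sig`` significant
    digits in the mantissa), without ever converting the integer to float."""
    if n <= 0:
        raise ValueError("count must be positive")
    digits = str(n)
    exponent = len(digits) - 1
    # round the mantissa at `sig` significant digits using integer arithmetic
    head = digits[: sig + 1].ljust(sig + 1, "0")
    mantissa_int = (int(head) + 5) // 10  # round half up
    if mantissa_int >= 10 ** sig:
        mantissa_int //= 10
        exponent += 1
    m = f"{mantissa_int / 10 ** (sig - 1):.{sig - 1}f}"
    return f"{m} × 10^{exponent}"


def nonsense_report(codon_spaces: Sequence[CodonSpace]) -> tuple[list[CodonSpace], float]:
    """Codons whose outcome space includes a stop codon, plus their fraction.

    DGR-targeted codons are composed so that adenine-directed variation
    cannot create nonsense codons; this report makes that property auditable.
    """
    if not codon_spaces:
        raise ValueError("no codons supplied")
    hits = [c for c in codon_spaces if c.stop_reachable]
    return hits, len(hits) / len(codon_spaces)


def _ref_codon(target: TargetGene, codon_index: int, genome: Mapping[str, str]) -> str:
    """Gene-oriented reference codon at ``codon_index`` of a target CDS."""
    cds = target.cds
    if cds.strand == "-":
        hi = cds.end - target.frame_offset - 3 * codon_index
        iv = GenomicInterval(cds.contig, hi - 3, hi, "-")
    else:
        lo = cds.start + target.frame_offset + 3 * codon_index
        iv = GenomicInterval(cds.contig, lo, lo + 3, "+")
    return iv.fetch(genome, oriented=True)


def codon_spaces_for_vr(
    target: TargetGene,
    positions: Sequence[VariablePosition],
    genome: Mapping[str, str],
) -> list[CodonSpace]:
    """Group a VR's variable positions by codon and enumerate each codon's
    outcome space. Offsets of a codon that fall outside the VR stay fixed."""
    by_codon: dict[int, set[int]] = {}
    for p in positions:
        by_codon.setdefault(p.codon_index, set()).add(p.codon_position - 1)
    return [
        codon_outcomes(_ref_codon(target, ci, genome), offs, codon_index=ci)
        for ci, offs in sorted(by_codon.items())
    ]


@dataclass
class SequenceSpaceReport:
    """Exact sequence-space counts at VR, target, and genome level."""

    per_vr: dict[str, int]
    per_target: dict[str, int]
    total: int
    per_vr_codons: dict[str, list[CodonSpace]]

    @property
    def n_variable_positions(self) -> int:
        return sum(
            len(c.targeted_offsets)
            for spaces in self.per_vr_codons.values()
            for c in spaces
        )

    @property
    def n_codons(self) -> int:
        return sum(len(s) for s in self.per_vr_codons.values())

    def to_dict(self) -> dict:
        """JSON-ready summary; exact counts as decimal strings plus rendering."""
        return {
            "per_vr": {k: {"count": str(v), "sci": sci_notation(v)}
                       for k, v in self.per_vr.items()},
            "per_target": {k: {"count": str(v), "sci": sci_notation(v)}
                           for k, v in self.per_target.items()},
            "genome_total": {"count": str(self.total), "sci": sci_notation(self.total)},
            "n_variable_positions": self.n_variable_positions,
            "n_codons": self.n_codons,
        }


def build_report(
    loci: Sequence[DGRLocus],
    genome: Mapping[str, str],
    variable_positions: Mapping[str, Sequence[VariablePosition]],
) -> SequenceSpaceReport:
    """Assemble the full sequence-space report from per-VR variable positions.

    ``variable_positions`` maps VR ids (as produced by
    :func:`dgrscope.repeat_model.locus_variable_positions`) to their records.
    """
    per_vr: dict[str, int] = {}
    per_target: dict[str, int] = {}
    per_vr_codons: dict[str, list[CodonSpace]] = {}
    for locus in loci:
        for tgt, i, _vr in locus.iter_vrs():
            vr_id = f"{tgt.gene_id}:VR{i + 1}"
            pos = variable_positions.get(vr_id)
            if not pos:
                continue
            spaces = codon_spaces_for_vr(tgt, pos, genome)
            per_vr_codons[vr_id] = spaces
            count = vr_polypeptide_count(spaces)
            per_vr[vr_id] = count
            per_target[tgt.gene_id] = per_target.get(tgt.gene_id, 1) * count
    if not per_target:
        raise ValueError("no VR has variable positions; nothing to report")
    return SequenceSpaceReport(
        per_vr=per_vr,
        per_target=per_target,
        total=genome_total(per_target),
        per_vr_codons=per_vr_codons,
    )
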