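"""DGR locus representation and template/variable repeat (TR-VR) analysis.

A diversity-generating retroelement (DGR) mutagenizes a *variable repeat*
(VR) inside a target gene by error-prone reverse transcription of a
*template repeat* (TR): the reverse transcriptase substitutes random
nucleotides at adenine positions of the TR, and the mutated cDNA recombines
into the VR. Aligning TR against VR therefore partitions VR columns into
adenine-targeted (mutable) and conserved classes. This module holds the
locus data model, performs that alignment, and maps the targeted columns
into genome coordinates and codon context.

Coordinates are 0-based half-open internally; file formats use 1-based
inclusive positions (see :mod:`dgrscope.io`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "TargetGene",
    "DGRLocus",
    "AlignmentColumn",
    "TRVRAlignment",
    "VariablePosition",
    "OrphanVRError",
    "align_tr_to_vr",
    "identify_variable_positions",
    "locus_variable_positions",
    "codon_position_spectrum",
]

VALID_BASES = frozenset("ACGTN")

#: minimum identity at non-adenine columns below which a TR-VR pair is
#: flagged as a weak homolog (genuine repeat pairs match at essentially
#: all non-A sites)
WEAK_PAIR_IDENTITY_FLOOR = 0.80


class OrphanVRError(ValueError):
    """A variable repeat that is not contained in any target CDS."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with strand.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the overlap with ``other`` (0 if disjoint or off-contig)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def fetch(self, genome: Mapping[str, str], oriented: bool = False) -> str:
        """Extract the interval's sequence from a contig->sequence mapping.

        With ``oriented=True`` the sequence is reverse-complemented for
        minus-strand intervals, i.e. returned 5'->3' in feature orientation.
        """
        seq = genome[self.contig][self.start : self.end].upper()
        if oriented and self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class TargetGene:
    """A DGR target CDS holding one or more variable repeats.

    ``vrs`` are ordered 5'->3' in gene orientation; every VR must lie inside
    the CDS. ``frame_offset`` shifts the reading frame relative to the CDS
    start (0 for an ordinary annotated CDS).
    """

    gene_id: str
    cds: GenomicInterval
    vrs: list[GenomicInterval]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.vrs:
            raise ValueError(f"target {self.gene_id} has no VRs")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0..2, got {self.frame_offset}")
        for vr in self.vrs:
            if not self.cds.contains(vr):
                raise OrphanVRError(
                    f"VR {vr.contig}:{vr.start}-{vr.end} outside CDS of "
                    f"{self.gene_id} ({self.cds.start}-{self.cds.end})"
                )
        for a, b in zip(self.vrs, self.vrs[1:]):
            if a.overlap(b) > 0:
                raise ValueError(f"overlapping VRs in target {self.gene_id}")
        # order 5'->3' in gene orientation
        self.vrs.sort(key=lambda v: v.start, reverse=self.cds.strand == "-")


@dataclass
class DGRLocus:
    """One DGR system: RT, accessory gene, TR, and its target genes.

    A locus is *complete* when reverse transcriptase, accessory protein and
    template repeat are all present; otherwise it is *degenerate* (key
    machinery missing or pseudogenized) and its VRs can only be diversified
    by a donor TR acting in trans.
    """

    locus_id: str
    targets: list[TargetGene]
    rt: GenomicInterval | None = None
    accessory: GenomicInterval | None = None
    tr: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"locus {self.locus_id} has no targets")

    @property
    def completeness(self) -> str:
        present = self.rt is not None and self.accessory is not None and self.tr is not None
        return "complete" if present else "degenerate"

    def iter_vrs(self) -> Iterable[tuple[TargetGene, int, GenomicInterval]]:
        """Yield (target, vr index within target, vr interval) for all VRs."""
        for tgt in self.targets:
            for i, vr in enumerate(tgt.vrs):
                yield tgt, i, vr


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a TR-VR alignment; index ``None`` marks a gap."""

    tr_index: int | None
    vr_index: int | None
    tr_base: str
    vr_base: str

    @property
    def is_gap(self) -> bool:
        return self.tr_index is None or self.vr_index is None


@dataclass
class TRVRAlignment:
    """Column-wise pairing of a TR with one VR.

    ``variable_columns`` holds the indices (into ``columns``) of aligned
    columns whose TR base is adenine — the positions the DGR can mutate.
    Gap columns and columns with an N in either sequence belong to neither
    the variable nor the conserved class.
    """

    tr_seq: str
    vr_seq: str
    columns: list[AlignmentColumn]
    variable_columns: frozenset[int] = field(init=False)
    nonA_mismatch_count: int = field(init=False)
    nonA_column_count: int = field(init=False)
    weak_pair: bool = field(init=False)
    has_gaps: bool = field(init=False)

    def __post_init__(self) -> None:
        variable = set()
        non_a = 0
        non_a_mm = 0
        gaps = False
        for i, col in enumerate(self.columns):
            if col.is_gap:
                gaps = True
                continue
            if col.tr_base == "N" or col.vr_base == "N":
                continue
            if col.tr_base == "A":
                variable.add(i)
            else:
                non_a += 1
                if col.tr_base != col.vr_base:
                    non_a_mm += 1
        self.variable_columns = frozenset(variable)
        self.nonA_mismatch_count = non_a_mm
        self.nonA_column_count = non_a
        self.has_gaps = gaps
        identity = 1.0 if non_a == 0 else (non_a - non_a_mm) / non_a
        self.weak_pair = identity < WEAK_PAIR_IDENTITY_FLOOR

    @property
    def observed_variable_changes(self) -> frozenset[int]:
        """Variable columns where the VR base differs from the TR base."""
        return frozenset(
            i for i in self.variable_columns
            if self.columns[i].vr_base != self.columns[i].tr_base
        )


def _validate_repeat_seq(name: str, seq: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{name} contains invalid characters: {sorted(bad)}")
    return seq


def align_tr_to_vr(tr_seq: str, vr_seq: str) -> TRVRAlignment:
    """Globally align a template repeat against a variable repeat.

    TR and VR are near-equal-length homologs, so a simple global scheme
    (match +1, mismatch 0, gap -2) suffices and gaps are rare. Columns
    whose TR base is adenine become the variable (mutable) class.
    """
    tr_seq = _validate_repeat_seq("TR", tr_seq)
    vr_seq = _validate_repeat_seq("VR", vr_seq)

    if len(tr_seq) == len(vr_seq):
        # ungapped pairing is the optimal global alignment for homologous
        # equal-length repeats under this scheme; also fully deterministic
        columns = [
            AlignmentColumn(i, i, t, v)
            for i, (t, v) in enumerate(zip(tr_seq, vr_seq))
        ]
        return TRVRAlignment(tr_seq, vr_seq, columns)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    aln = aligner.align(tr_seq, vr_seq)[0]
    gapped_tr, gapped_vr = str(aln[0]), str(aln[1])

    columns: list[AlignmentColumn] = []
    ti = vi = 0
    for t, v in zip(gapped_tr, gapped_vr):
        tr_index = ti if t != "-" else None
        vr_index = vi if v != "-" else None
        columns.append(AlignmentColumn(tr_index, vr_index, t, v))
        ti += t != "-"
        vi += v != "-"
    return TRVRAlignment(tr_seq, vr_seq, columns)


@dataclass(frozen=True)
class VariablePosition:
    """A genome position mutable by the DGR, with its codon context.

    ``codon_position`` is 1..3 within the codon, counted 5'->3' in gene
    orientation; ``ref_base`` is the plus-strand genome base at
    ``genome_pos`` (the base read pileups are compared against).
    """

    genome_pos: int
    contig: str
    vr_offset: int
    codon_index: int
    codon_position: int
    ref_base: str
    gene_id: str = ""
    vr_id: str = ""


def identify_variable_positions(
    target: TargetGene,
    vr: GenomicInterval,
    alignment: TRVRAlignment,
    genome: Mapping[str, str],
    vr_id: str = "",
) -> list[VariablePosition]:
    """Map an alignment's variable columns onto genome and codon coordinates.

    The VR must lie inside the target CDS (enforced at construction). For a
    minus-strand CDS the VR sequence is gene-oriented, so VR offset 0
    corresponds to plus-strand genome position ``vr.end - 1`` and codon
    arithmetic runs 5'->3' of the gene.
    """
    if not target.cds.contains(vr):
        raise OrphanVRError(
            f"VR {vr.contig}:{vr.start}-{vr.end} not inside CDS of {target.gene_id}"
        )
    contig_seq = genome[vr.contig]
    minus = target.cds.strand == "-"
    positions: list[VariablePosition] = []
    for i in sorted(alignment.variable_columns):
        col = alignment.columns[i]
        vr_offset = col.vr_index
        assert vr_offset is not None  # gap columns are never variable
        if minus:
            genome_pos = vr.end - 1 - vr_offset
            pos_in_gene = (target.cds.end - vr.end) + vr_offset
        else:
            genome_pos = vr.start + vr_offset
            pos_in_gene = (vr.start - target.cds.start) + vr_offset
        q = pos_in_gene - target.frame_offset
        if q < 0:
            continue  # upstream of the reading frame; not a codon position
        positions.append(
            VariablePosition(
                genome_pos=genome_pos,
                contig=vr.contig,
                vr_offset=vr_offset,
                codon_index=q // 3,
                codon_position=q % 3 + 1,
                ref_base=contig_seq[genome_pos].upper(),
                gene_id=target.gene_id,
                vr_id=vr_id,
            )
        )
    return positions


def locus_variable_positions(
    locus: DGRLocus,
    genome: Mapping[str, str],
    tr_seq: str | None = None,
) -> dict[str, list[VariablePosition]]:
    """Variable positions for every VR of a locus, keyed by VR id.

    The donor TR defaults to the locus's own TR; for a degenerate locus a
    trans-acting donor sequence must be supplied via ``tr_seq``.
    """
    if tr_seq is None:
        if locus.tr is None:
            raise ValueError(
                f"locus {locus.locus_id} has no TR; supply a donor tr_seq"
            )
        tr_seq = locus.tr.fetch(genome, oriented=True)
    out: dict[str, list[VariablePosition]] = {}
    for tgt, i, vr in locus.iter_vrs():
        vr_id = f"{tgt.gene_id}:VR{i + 1}"
        vr_oriented = GenomicInterval(vr.contig, vr.start, vr.end, tgt.cds.strand)
        aln = align_tr_to_vr(tr_seq, vr_oriented.fetch(genome, oriented=True))
        out[vr_id] = identify_variable_positions(tgt, vr, aln, genome, vr_id=vr_id)
    return out


def codon_position_spectrum(
    positions: Sequence[VariablePosition],
) -> tuple[dict[int, int], float]:
    """Histogram of codon positions (1/2/3) hit by variable positions.

    Returns the counts and the fraction falling at the codon's third
    position. DGR-targeted codons concentrate their adenines at positions
    1 and 2, which maximizes amino-acid diversity per mutation.
    """
    if not positions:
        raise ValueError("no variable positions supplied")
    counts = Counter(p.codon_position for p in positions)
    spectrum = {k: counts.get(k, 0) for k in (1, 2, 3)}
    frac3 = spectrum[3] / len(positions)
    return spectrum, frac3
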