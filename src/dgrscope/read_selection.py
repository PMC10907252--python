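"""Selection of VR-informative read pairs and pileup construction.

DGR loci are often duplicated within a genome, so naive mapping piles
reads from one variable repeat onto another and fabricates diversity. The
guard used here keeps only reads that overlap a VR *and* whose mate maps
nearby (within 1 kb by default) on the same contig — a pair anchored in
unique flanking sequence. Pileups are then built from the selected reads
only, reporting every position of the region including zero-depth ones
(the ``samtools mpileup -a`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

from .diversity_stats import PositionCounts
from .repeat_model import GenomicInterval

__all__ = [
    "FilterConfig",
    "select_vr_read_pairs",
    "build_pileup",
    "pileup_from_alignments",
]


@dataclass(frozen=True)
class FilterConfig:
    """Mate-pair filter thresholds.

    ``max_mate_distance`` is the largest allowed gap between the nearest
    ends of a read's alignment and its mate's; ``min_vr_overlap`` the
    minimum overlap (bp) between read and VR.
    """

    max_mate_distance: int = 1000
    min_vr_overlap: int = 1
    require_same_contig: bool = True

    def __post_init__(self) -> None:
        if self.max_mate_distance <= 0 or self.min_vr_overlap <= 0:
            raise ValueError("filter distances must be positive")


class UnsortedInputError(ValueError):
    """Alignments are not coordinate-sorted."""


def _mate_gap(read: pysam.AlignedSegment) -> int:
    """Gap (bp) between the nearest ends of a read and its mate.

    The mate's end is not carried in a single record; it is approximated
    as ``mate_start + query_length`` (exact for ungapped alignments).
    Overlapping or abutting pairs have gap 0.
    """
    mate_start = read.next_reference_start
    mate_end = mate_start + (read.query_length or read.infer_read_length() or 0)
    if mate_start < read.reference_start:
        return max(0, read.reference_start - mate_end)
    return max(0, mate_start - read.reference_end)


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def select_vr_read_pairs(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    vrs: Sequence[GenomicInterval],
    cfg: FilterConfig = FilterConfig(),
) -> dict[int, list[pysam.AlignedSegment]]:
    """Stream coordinate-sorted alignments and keep VR-informative pairs.

    A read is retained for a VR iff it overlaps that VR by at least
    ``cfg.min_vr_overlap`` bp and its mate is mapped on the same contig
    with a gap of at most ``cfg.max_mate_distance`` bp. Unpaired reads,
    mate-unmapped reads, and secondary/supplementary/duplicate records are
    dropped. A read overlapping several VRs is kept for each.

    Returns ``{vr index in vrs: [reads]}``.
    """
    own_handle = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments, require_index=False)
        own_handle = True
    if isinstance(alignments, pysam.AlignmentFile):
        header = alignments.header.to_dict()
        so = header.get("HD", {}).get("SO", "unknown")
        if so not in ("coordinate", "unknown"):
            raise UnsortedInputError(f"alignments sorted by {so!r}, need coordinate")

    selected: dict[int, list[pysam.AlignedSegment]] = {i: [] for i in range(len(vrs))}
    last_pos: dict[str, int] = {}
    try:
        for read in alignments:
            if not _usable(read):
                continue
            pos = read.reference_start
            if last_pos.get(read.reference_name, -1) > pos:
                raise UnsortedInputError(
                    f"alignments not coordinate-sorted at {read.reference_name}:{pos}"
                )
            last_pos[read.reference_name] = pos
            if not read.is_paired or read.mate_is_unmapped:
                continue
            if cfg.require_same_contig and read.next_reference_id != read.reference_id:
                continue
            if _mate_gap(read) > cfg.max_mate_distance:
                continue
            for i, vr in enumerate(vrs):
                if read.reference_name != vr.contig:
                    continue
                overlap = min(read.reference_end, vr.end) - max(read.reference_start, vr.start)
                if overlap >= cfg.min_vr_overlap:
                    selected[i].append(read)
    finally:
        if own_handle:
            alignments.close()
    return selected


def build_pileup(
    reads: Iterable[pysam.AlignedSegment],
    region: GenomicInterval,
    genome: Mapping[str, str],
) -> list[PositionCounts]:
    """Per-position A/C/G/T counts over ``region`` from the given reads.

    Every position of the region appears in the output, zero-depth
    positions included. Only A/C/G/T base calls are tallied: N calls and
    deletion columns contribute nothing to depth.
    """
    contig_seq = genome[region.contig]
    if region.end > len(contig_seq):
        raise IndexError(
            f"region {region.contig}:{region.start}-{region.end} outside genome "
            f"(contig length {len(contig_seq)})"
        )
    counts = [
        PositionCounts(genome_pos=p, ref_base=contig_seq[p].upper(),
                       contig=region.contig)
        for p in range(region.start, region.end)
    ]
    attr = {"A": "a", "C": "c", "G": "g", "T": "t"}
    for read in reads:
        if read.reference_name != region.contig:
            continue
        seq = read.query_sequence
        if seq is None:
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos < region.start or rpos >= region.end:
                continue
            base = seq[qpos].upper()
            if base in attr:
                pc = counts[rpos - region.start]
                setattr(pc, attr[base], getattr(pc, attr[base]) + 1)
    return counts


def pileup_from_alignments(
    path: str,
    region: GenomicInterval,
    genome: Mapping[str, str],
) -> list[PositionCounts]:
    """Genome-wide-mode pileup: all usable mapped reads, no VR/mate filter.

    This is the substrate for genome-scale clonality summaries, where the
    duplication-guard filter is unnecessary and would bias coverage.
    """
    with pysam.AlignmentFile(path, require_index=False) as af:
        reads = [r for r in af if _usable(r) and r.reference_name == region.contig]
    return build_pileup(reads, region, genome)
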