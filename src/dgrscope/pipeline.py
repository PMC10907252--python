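"""High-level orchestration: glue between the analysis modules.

These functions are what the command-line surface and the acceptance
workflow call; they contain no science of their own, only the canonical
ordering: select reads -> pile up -> profile -> call -> aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import read_selection, trans_matcher
from .diversity_stats import (
    DiversificationCall,
    DiversityProfile,
    PositionCounts,
    ProfileConfig,
    aggregate_calls,
    call_diversified,
    profile_region,
)
from .read_selection import FilterConfig
from .repeat_model import DGRLocus, GenomicInterval, locus_variable_positions

__all__ = ["AnalysisResult", "pileups_from_bam", "pileups_from_counts",
           "analyze", "match_all_trs"]


@dataclass
class AnalysisResult:
    """Profiles, per-VR calls, and target/locus aggregation for one sample."""

    profiles: list[DiversityProfile]
    calls: list[DiversificationCall]
    target_diversified: dict[str, bool | None] = field(default_factory=dict)
    locus_diversified: dict[str, bool | None] = field(default_factory=dict)


def _vr_index(loci: Sequence[DGRLocus]):
    """(vr_id, locus, target, interval) for every VR of every locus."""
    for locus in loci:
        for tgt, i, vr in locus.iter_vrs():
            yield f"{tgt.gene_id}:VR{i + 1}", locus, tgt, vr


def pileups_from_bam(
    bam_path: str,
    loci: Sequence[DGRLocus],
    genome: Mapping[str, str],
    filter_cfg: FilterConfig = FilterConfig(),
) -> dict[str, list[PositionCounts]]:
    """Mate-filtered, per-VR pileups from a coordinate-sorted SAM/BAM."""
    index = list(_vr_index(loci))
    vrs = [vr for _, _, _, vr in index]
    selected = read_selection.select_vr_read_pairs(bam_path, vrs, filter_cfg)
    return {
        vr_id: read_selection.build_pileup(selected[i], vr, genome)
        for i, (vr_id, _, _, vr) in enumerate(index)
    }


def pileups_from_counts(
    counts: Sequence[PositionCounts],
    loci: Sequence[DGRLocus],
) -> dict[str, list[PositionCounts]]:
    """Slice a precomputed counts table into per-VR pileups."""
    by_pos = {(pc.contig, pc.genome_pos): pc for pc in counts}
    out: dict[str, list[PositionCounts]] = {}
    for vr_id, _, _, vr in _vr_index(loci):
        out[vr_id] = [
            by_pos.get((vr.contig, p),
                       PositionCounts(genome_pos=p, ref_base="N", contig=vr.contig))
            for p in range(vr.start, vr.end)
        ]
    return out


def analyze(
    pileups: Mapping[str, list[PositionCounts]],
    loci: Sequence[DGRLocus],
    genome: Mapping[str, str],
    cfg: ProfileConfig = ProfileConfig(),
    metrics: Sequence[str] = ("pi", "nonref"),
    donor_trs: Mapping[str, str] | None = None,
) -> AnalysisResult:
    """Profile every VR, apply the 2-sd rule, and aggregate upward.

    ``donor_trs`` maps a locus id to a trans-acting donor TR sequence for
    degenerate loci without their own TR. A target or locus is diversified
    if at least one of its VRs is called so under *any* requested metric.
    """
    profiles: list[DiversityProfile] = []
    calls: list[DiversificationCall] = []
    calls_by_target: dict[str, list[DiversificationCall]] = {}
    calls_by_locus: dict[str, list[DiversificationCall]] = {}
    for locus in loci:
        donor = (donor_trs or {}).get(locus.locus_id)
        varpos = locus_variable_positions(locus, genome, tr_seq=donor)
        for tgt, i, vr in locus.iter_vrs():
            vr_id = f"{tgt.gene_id}:VR{i + 1}"
            prof = profile_region(pileups[vr_id],
                                  [p.genome_pos for p in varpos[vr_id]],
                                  cfg, vr_id=vr_id)
            profiles.append(prof)
            for metric in metrics:
                call = call_diversified(prof, metric, cfg)
                calls.append(call)
                calls_by_target.setdefault(tgt.gene_id, []).append(call)
                calls_by_locus.setdefault(locus.locus_id, []).append(call)
    return AnalysisResult(
        profiles=profiles,
        calls=calls,
        target_diversified={k: aggregate_calls(v) for k, v in calls_by_target.items()},
        locus_diversified={k: aggregate_calls(v) for k, v in calls_by_locus.items()},
    )


def match_all_trs(
    loci: Sequence[DGRLocus],
    genome: Mapping[str, str],
) -> tuple[dict[str, list[trans_matcher.TRMatch]], dict[str, str]]:
    """Match every VR against every TR in the genome; classify each VR's
    diversification mode (cis / trans / orphan)."""
    all_trs = [
        (locus.locus_id, locus.tr.fetch(genome, oriented=True))
        for locus in loci if locus.tr is not None
    ]
    if not all_trs:
        raise ValueError("no locus has a TR; nothing to match against")
    matches_by_vr: dict[str, list[trans_matcher.TRMatch]] = {}
    modes: dict[str, str] = {}
    for locus in loci:
        locus_matches: dict[str, list[trans_matcher.TRMatch]] = {}
        for tgt, i, vr in locus.iter_vrs():
            vr_id = f"{tgt.gene_id}:VR{i + 1}"
            oriented = GenomicInterval(vr.contig, vr.start, vr.end, tgt.cds.strand)
            locus_matches[vr_id] = trans_matcher.match_vr_to_trs(
                oriented.fetch(genome, oriented=True), all_trs, vr_id=vr_id)
        matches_by_vr.update(locus_matches)
        modes.update(trans_matcher.classify_locus_mode(locus, locus_matches))
    return matches_by_vr, modes
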