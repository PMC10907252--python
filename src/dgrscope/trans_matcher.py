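"""Cis/trans donor inference: which template repeat can diversify which VR.

Mutagenic retrohoming only alters adenine-aligned positions, so a TR that
actually writes into a VR must match it perfectly at every non-adenine
site — whatever has happened at the adenines. Scanning a VR against all
TRs in a genome therefore identifies its possible donors: the locus's own
TR (*cis*), a TR from another locus (*trans*), or none (*orphan*, e.g. a
locus whose TR was destroyed by transposon activity after diversification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .repeat_model import DGRLocus, TRVRAlignment, align_tr_to_vr

__all__ = ["TRMatch", "match_vr_to_trs", "classify_locus_mode"]


@dataclass
class TRMatch:
    """Compatibility of one candidate donor TR with one VR.

    ``compatible`` requires zero mismatches at non-adenine columns and an
    alignment covering the whole VR. Gapped or reverse-complement matches
    are reported but flagged.
    """

    vr_id: str
    donor_tr_locus: str
    n_nonA_columns: int
    n_nonA_mismatches: int
    n_A_columns: int
    compatible: bool
    gapped: bool = False
    revcomp: bool = False

    @property
    def identity(self) -> float:
        total = self.n_nonA_columns + self.n_A_columns
        if total == 0:
            return 0.0
        matched = self.n_nonA_columns - self.n_nonA_mismatches
        return matched / total


def _match_one(vr_id: str, locus_id: str, tr_seq: str, vr_seq: str,
               revcomp: bool) -> TRMatch:
    aln: TRVRAlignment = align_tr_to_vr(tr_seq, vr_seq)
    vr_covered = all(
        col.vr_index is None or col.tr_index is not None for col in aln.columns
    )
    return TRMatch(
        vr_id=vr_id,
        donor_tr_locus=locus_id,
        n_nonA_columns=aln.nonA_column_count,
        n_nonA_mismatches=aln.nonA_mismatch_count,
        n_A_columns=len(aln.variable_columns),
        compatible=aln.nonA_mismatch_count == 0 and vr_covered,
        gapped=aln.has_gaps,
        revcomp=revcomp,
    )


def match_vr_to_trs(
    vr_seq: str,
    all_trs: Sequence[tuple[str, str]],
    vr_id: str = "",
    search_revcomp: bool = True,
) -> list[TRMatch]:
    """Test a VR against every candidate TR in the genome.

    For each ``(locus_id, tr_seq)`` the best of the forward and (when
    ``search_revcomp``) reverse-complement alignments is reported — fewest
    non-A mismatches wins. Results are ordered compatible-first, then by
    total identity, then locus id, so ties between multiple compatible
    donors are all visible and deterministically ranked.
    """
    if not all_trs:
        raise ValueError("no candidate TRs supplied")
    matches = []
    for locus_id, tr_seq in all_trs:
        fwd = _match_one(vr_id, locus_id, tr_seq, vr_seq, revcomp=False)
        best = fwd
        if search_revcomp:
            rc = _match_one(vr_id, locus_id,
                            str(Seq(tr_seq).reverse_complement()), vr_seq,
                            revcomp=True)
            if (rc.compatible, -rc.n_nonA_mismatches) > (fwd.compatible, -fwd.n_nonA_mismatches):
                best = rc
        matches.append(best)
    matches.sort(key=lambda m: (not m.compatible, -m.identity, m.donor_tr_locus))
    return matches


def classify_locus_mode(
    locus: DGRLocus,
    matches_by_vr: Mapping[str, Sequence[TRMatch]],
) -> dict[str, str]:
    """Per-VR diversification mode: ``cis``, ``trans``, or ``orphan``.

    *cis* if the locus's own TR is among the compatible donors, *trans* if
    only a foreign TR is, *orphan* if no TR anywhere in the genome is.
    Matches must have been computed against every TR in the genome. Mode
    describes what machinery *could* write into the VR; it says nothing
    about whether diversification is currently active.
    """
    modes: dict[str, str] = {}
    for vr_id, matches in matches_by_vr.items():
        compatible = [m for m in matches if m.compatible]
        if not compatible:
            modes[vr_id] = "orphan"
        elif locus.tr is not None and any(
            m.donor_tr_locus == locus.locus_id for m in compatible
        ):
            modes[vr_id] = "cis"
        else:
            modes[vr_id] = "trans"
    return modes
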