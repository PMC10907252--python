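"""Per-position diversity metrics and the DGR diversification decision rule.

Two per-position statistics summarize within-sample variation from a read
pileup:

* nucleotide diversity ``π = 1 − (f_A² + f_T² + f_C² + f_G²)`` — the
  probability that two reads drawn with replacement differ at the position;
* the proportion of non-reference alleles, ``1 − count(ref)/depth``.

A variable repeat is called *diversified* when the mean of a metric over
its adenine-targeted positions strictly exceeds the mean over its
non-targeted positions plus two standard deviations of the non-targeted
values:

    mean_A > mean_nonA + 2 · sd(nonA)

applied independently for π and for the non-reference proportion. Targets
and loci are diversified when at least one of their VRs is. Positions need
more than 5× coverage (depth ≥ 6) to enter any statistic.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PositionCounts",
    "ProfileConfig",
    "DiversityProfile",
    "ProfileRow",
    "DiversificationCall",
    "pi",
    "nonref_prop",
    "profile_region",
    "call_diversified",
    "aggregate_calls",
    "genome_wide_summary",
]

_BASES = "ACGT"


@dataclass
class PositionCounts:
    """A, C, G, T read counts at one genome position."""

    genome_pos: int
    ref_base: str
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    contig: str = ""

    @property
    def depth(self) -> int:
        return self.a + self.c + self.g + self.t

    def count(self, base: str) -> int:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}[base]

    def frequencies(self) -> tuple[float, float, float, float]:
        d = self.depth
        if d == 0:
            raise ValueError(f"no coverage at position {self.genome_pos}")
        return (self.a / d, self.c / d, self.g / d, self.t / d)


@dataclass(frozen=True)
class ProfileConfig:
    """Coverage and decision-rule thresholds.

    ``min_depth=6`` encodes the strict ">5× coverage" rule; the standard
    deviation over non-targeted positions is the sample sd (n−1), so at
    least ``min_nonA_positions=3`` of them are required for a call.
    """

    min_depth: int = 6
    sd_multiplier: float = 2.0
    min_nonA_positions: int = 3
    min_A_positions: int = 1
    snv_min_freq: float = 0.1

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.sd_multiplier <= 0:
            raise ValueError("min_depth and sd_multiplier must be positive")
        if self.min_A_positions < 1 or self.min_nonA_positions < 1:
            raise ValueError("minimum position counts must be positive")


def pi(counts: PositionCounts) -> float:
    """Nucleotide diversity at one position: 1 − Σ base frequency².

    Equals the probability that two reads sampled with replacement carry
    different bases; 0 when monomorphic, 0.75 at maximal evenness.
    Undefined (raises) at zero depth — mask, don't coerce to 0.
    """
    fa, fc, fg, ft = counts.frequencies()
    return 1.0 - (fa * fa + ft * ft + fc * fc + fg * fg)


def nonref_prop(counts: PositionCounts) -> float:
    """Proportion of reads not matching the reference base."""
    ref = counts.ref_base.upper()
    if ref not in _BASES:
        raise ValueError(f"reference base {ref!r} at {counts.genome_pos} is ambiguous")
    d = counts.depth
    if d == 0:
        raise ValueError(f"no coverage at position {counts.genome_pos}")
    return 1.0 - counts.count(ref) / d


@dataclass(frozen=True)
class ProfileRow:
    genome_pos: int
    klass: str  # 'A-targeted' | 'non-targeted' | 'masked-low-coverage'
    depth: int
    a: int
    c: int
    g: int
    t: int
    pi: float | None
    nonref: float | None


@dataclass
class DiversityProfile:
    """Per-position π/non-reference values over a VR, with class labels."""

    vr_id: str
    rows: list[ProfileRow]
    config: ProfileConfig

    def values(self, metric: str, klass: str) -> list[float]:
        if metric not in ("pi", "nonref"):
            raise ValueError(f"unknown metric {metric!r}")
        return [
            getattr(r, "pi" if metric == "pi" else "nonref")
            for r in self.rows
            if r.klass == klass
        ]

    @property
    def insufficient_coverage(self) -> bool:
        return all(r.klass == "masked-low-coverage" for r in self.rows)


def profile_region(
    pileup: Sequence[PositionCounts],
    variable_positions: Iterable[int],
    cfg: ProfileConfig = ProfileConfig(),
    vr_id: str = "",
) -> DiversityProfile:
    """Classify and score each pileup position of a VR.

    ``variable_positions`` are the genome positions that align to a TR
    adenine (mutable by the DGR); every other position is the conserved
    background the decision rule is calibrated against. Positions below
    ``cfg.min_depth`` are masked and excluded from all statistics.
    """
    targeted = set(variable_positions)
    rows = []
    for pc in pileup:
        if pc.depth < cfg.min_depth or pc.ref_base.upper() not in _BASES:
            rows.append(ProfileRow(pc.genome_pos, "masked-low-coverage",
                                   pc.depth, pc.a, pc.c, pc.g, pc.t, None, None))
            continue
        klass = "A-targeted" if pc.genome_pos in targeted else "non-targeted"
        rows.append(ProfileRow(pc.genome_pos, klass, pc.depth,
                               pc.a, pc.c, pc.g, pc.t, pi(pc), nonref_prop(pc)))
    return DiversityProfile(vr_id=vr_id, rows=rows, config=cfg)


@dataclass
class DiversificationCall:
    """Outcome of the 2-sd rule for one VR and one metric.

    ``diversified`` uses strict inequality: mean_A > mean_nonA + k·sd_nonA.
    When coverage prerequisites are unmet the call is *absent* — represented
    by ``diversified=None`` with the reason — never coerced to False.
    """

    vr_id: str
    metric: str
    diversified: bool | None
    mean_A: float | None = None
    mean_nonA: float | None = None
    sd_nonA: float | None = None
    threshold: float | None = None
    n_A_used: int = 0
    n_nonA_used: int = 0
    reason: str = ""

    @property
    def present(self) -> bool:
        return self.diversified is not None


def call_diversified(
    profile: DiversityProfile,
    metric: str = "pi",
    cfg: ProfileConfig | None = None,
) -> DiversificationCall:
    """Apply the 2-sd decision rule to a VR profile.

    sd is the sample standard deviation (n−1 denominator) of the metric
    over unmasked non-targeted positions. If that sd is zero the rule
    degenerates to a strict comparison of the two means.
    """
    cfg = cfg or profile.config
    vals_a = profile.values(metric, "A-targeted")
    vals_non = profile.values(metric, "non-targeted")
    if len(vals_a) < cfg.min_A_positions or len(vals_non) < cfg.min_nonA_positions:
        return DiversificationCall(
            vr_id=profile.vr_id, metric=metric, diversified=None,
            n_A_used=len(vals_a), n_nonA_used=len(vals_non),
            reason=(f"insufficient coverage: {len(vals_a)} targeted / "
                    f"{len(vals_non)} non-targeted positions usable"),
        )
    mean_a = statistics.fmean(vals_a)
    mean_non = statistics.fmean(vals_non)
    sd_non = statistics.stdev(vals_non)
    threshold = mean_non + cfg.sd_multiplier * sd_non
    return DiversificationCall(
        vr_id=profile.vr_id, metric=metric,
        diversified=mean_a > threshold,
        mean_A=mean_a, mean_nonA=mean_non, sd_nonA=sd_non, threshold=threshold,
        n_A_used=len(vals_a), n_nonA_used=len(vals_non),
    )


def aggregate_calls(calls: Iterable[DiversificationCall]) -> bool | None:
    """Logical OR over present calls: a target or locus is diversified when
    at least one of its VRs is. With no present call the aggregate has *no
    data* (``None``), which is not the same as undiversified."""
    present = [c.diversified for c in calls if c.present]
    if not present:
        return None
    return any(present)


def genome_wide_summary(
    pileup: Iterable[PositionCounts],
    cfg: ProfileConfig = ProfileConfig(),
) -> dict:
    """Median π and SNV density per 10 kb over a genome-scale pileup.

    An SNV is an unmasked position whose non-reference proportion reaches
    ``cfg.snv_min_freq``; density is per 10 kb of unmasked (depth ≥
    min_depth) genome. Used on unfiltered mappings to gauge the clonality
    of the population outside DGR loci.
    """
    pis = []
    n_snv = 0
    n_unmasked = 0
    for pc in pileup:
        if pc.depth < cfg.min_depth or pc.ref_base.upper() not in _BASES:
            continue
        n_unmasked += 1
        pis.append(pi(pc))
        if nonref_prop(pc) >= cfg.snv_min_freq:
            n_snv += 1
    if n_unmasked == 0:
        return {"median_pi": math.nan, "snv_per_10kb": math.nan,
                "n_unmasked": 0, "n_snv": 0}
    return {
        "median_pi": float(np.median(pis)),
        "snv_per_10kb": n_snv / n_unmasked * 10_000,
        "n_unmasked": n_unmasked,
        "n_snv": n_snv,
    }
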