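"""File formats: genomes, locus tables, counts tables, and result reports.

All on-disk coordinates are 1-based inclusive (the bioinformatics table
convention); conversion to the package's internal 0-based half-open
intervals happens exclusively here. The per-position counts TSV (contig,
pos, ref, count_A..count_T) is the pipeline's interchange hub: it is what
``samtools mpileup`` output reduces to, and R or other consumers can enter
mid-pipeline through it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .diversity_stats import DiversificationCall, DiversityProfile, PositionCounts, ProfileRow
from .repeat_model import DGRLocus, GenomicInterval, OrphanVRError, TargetGene

__all__ = [
    "LocusTableError",
    "read_genome",
    "read_locus_table",
    "write_locus_table",
    "read_counts",
    "write_counts",
    "write_profiles",
    "read_profile",
    "write_calls",
    "write_locus_json",
]

LOCUS_COLUMNS = ["locus_id", "feature", "contig", "start", "end",
                 "strand", "parent_gene", "frame"]
COUNT_COLUMNS = ["contig", "pos", "ref", "count_A", "count_C", "count_G", "count_T"]


class LocusTableError(ValueError):
    """Malformed locus table row; message carries the line number."""


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as a contig -> uppercase sequence mapping."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def _interval(row, line_no: int) -> GenomicInterval:
    try:
        start_1 = int(row["start"])
        end_1 = int(row["end"])
        return GenomicInterval(str(row["contig"]), start_1 - 1, end_1,
                               str(row["strand"]))
    except (ValueError, TypeError) as exc:
        raise LocusTableError(f"line {line_no}: {exc}") from exc


def read_locus_gff3(path: str | Path,
                    genome: Mapping[str, str] | None = None) -> list[DGRLocus]:
    """GFF3 dialect of the locus table.

    Feature types DGR_RT / DGR_ACC / DGR_TR / CDS / DGR_VR, grouped by a
    ``locus_id`` attribute; DGR_VR features name their CDS via ``Parent``.
    CDS phase (column 8) supplies the frame offset.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    by_locus: dict[str, dict] = {}
    type_map = {"DGR_RT": "rt", "DGR_ACC": "acc", "DGR_TR": "tr"}
    for feat in db.all_features():
        locus_id = feat.attributes.get("locus_id", ["?"])[0]
        entry = by_locus.setdefault(locus_id, {"rt": None, "acc": None,
                                               "tr": None, "targets": {},
                                               "vrs": []})
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if genome is not None and (iv.contig not in genome
                                   or iv.end > len(genome[iv.contig])):
            raise LocusTableError(f"{feat.featuretype} {feat.id}: outside genome")
        if feat.featuretype in type_map:
            entry[type_map[feat.featuretype]] = iv
        elif feat.featuretype == "CDS":
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            frame = int(feat.frame) if feat.frame not in (None, ".") else 0
            entry["targets"][gene_id] = {"cds": iv, "frame": frame, "vrs": []}
        elif feat.featuretype == "DGR_VR":
            parent = feat.attributes.get("Parent", ["?"])[0]
            entry["vrs"].append((parent, iv, feat.start))
    return _assemble_loci(by_locus)


def _assemble_loci(by_locus: dict[str, dict]) -> list[DGRLocus]:
    loci = []
    for locus_id, entry in by_locus.items():
        for gene_id, vr, line_no in entry["vrs"]:
            if gene_id not in entry["targets"]:
                raise LocusTableError(
                    f"line {line_no}: VR names unknown parent_gene {gene_id!r}")
            entry["targets"][gene_id]["vrs"].append(vr)
        targets = []
        for gene_id, t in entry["targets"].items():
            try:
                targets.append(TargetGene(gene_id=gene_id, cds=t["cds"],
                                          vrs=t["vrs"], frame_offset=t["frame"]))
            except OrphanVRError as exc:
                raise OrphanVRError(f"locus {locus_id}: {exc}") from exc
        loci.append(DGRLocus(locus_id=locus_id, targets=targets,
                             rt=entry["rt"], accessory=entry["acc"],
                             tr=entry["tr"]))
    return sorted(loci, key=lambda l: l.locus_id)


def read_locus_table(path: str | Path,
                     genome: Mapping[str, str] | None = None) -> list[DGRLocus]:
    """Parse the DGR locus table (TSV, or GFF3 by file extension).

    TSV dialect: one row per feature — RT, ACC, TR, TARGET, or VR; VR
    rows name their ``parent_gene``. Coordinates are validated against
    the genome when one is supplied; a VR outside its parent CDS raises
    :class:`OrphanVRError`.
    """
    if str(path).endswith((".gff", ".gff3")):
        return read_locus_gff3(path, genome)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise LocusTableError(f"missing columns: {sorted(missing)}")

    by_locus: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, counting the header
        feature = str(row["feature"]).upper()
        if feature not in ("RT", "ACC", "TR", "TARGET", "VR"):
            raise LocusTableError(f"line {line_no}: unknown feature {feature!r}")
        iv = _interval(row, line_no)
        if genome is not None:
            if iv.contig not in genome:
                raise LocusTableError(
                    f"line {line_no}: contig {iv.contig!r} not in genome")
            if iv.end > len(genome[iv.contig]):
                raise LocusTableError(
                    f"line {line_no}: feature {feature} {iv.start + 1}-{iv.end} "
                    f"beyond contig end {len(genome[iv.contig])}")
        entry = by_locus.setdefault(str(row["locus_id"]),
                                    {"rt": None, "acc": None, "tr": None,
                                     "targets": {}, "vrs": []})
        if feature == "RT":
            entry["rt"] = iv
        elif feature == "ACC":
            entry["acc"] = iv
        elif feature == "TR":
            entry["tr"] = iv
        elif feature == "TARGET":
            frame = int(row["frame"]) if pd.notna(row["frame"]) else 0
            gene_id = str(row["parent_gene"])
            entry["targets"][gene_id] = {"cds": iv, "frame": frame, "vrs": []}
        else:  # VR
            entry["vrs"].append((str(row["parent_gene"]), iv, line_no))

    return _assemble_loci(by_locus)


def write_locus_table(loci: Sequence[DGRLocus], path: str | Path) -> None:
    rows = []

    def add(locus_id, feature, iv, parent="", frame=""):
        rows.append([locus_id, feature, iv.contig, iv.start + 1, iv.end,
                     iv.strand, parent, frame])

    for locus in loci:
        if locus.rt:
            add(locus.locus_id, "RT", locus.rt)
        if locus.accessory:
            add(locus.locus_id, "ACC", locus.accessory)
        if locus.tr:
            add(locus.locus_id, "TR", locus.tr)
        for tgt in locus.targets:
            add(locus.locus_id, "TARGET", tgt.cds, tgt.gene_id, tgt.frame_offset)
            for vr in tgt.vrs:
                add(locus.locus_id, "VR", vr, tgt.gene_id)
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> list[PositionCounts]:
    """Read a per-position counts TSV (1-based positions on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return [
        PositionCounts(genome_pos=int(r.pos) - 1, ref_base=str(r.ref),
                       a=int(r.count_A), c=int(r.count_C),
                       g=int(r.count_G), t=int(r.count_T), contig=str(r.contig))
        for r in df.itertuples()
    ]


def write_counts(counts: Iterable[PositionCounts], path: str | Path) -> None:
    rows = [[pc.contig, pc.genome_pos + 1, pc.ref_base, pc.a, pc.c, pc.g, pc.t]
            for pc in counts]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_profiles(profiles: Sequence[DiversityProfile], path: str | Path) -> None:
    """Per-position report TSV: one row per VR position with class, counts,
    π and non-reference proportion (blank when masked)."""
    rows = []
    for prof in profiles:
        for r in prof.rows:
            rows.append([prof.vr_id, r.genome_pos + 1, r.klass, r.depth,
                         r.a, r.c, r.g, r.t,
                         "" if r.pi is None else f"{r.pi:.10g}",
                         "" if r.nonref is None else f"{r.nonref:.10g}"])
    pd.DataFrame(rows, columns=["vr_id", "pos", "class", "depth",
                                "a", "c", "g", "t", "pi", "nonref"]
                 ).to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path) -> dict[str, list[ProfileRow]]:
    """Round-trip reader for :func:`write_profiles` output."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ProfileRow]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.vr_id), []).append(ProfileRow(
            genome_pos=int(r.pos) - 1, klass=str(getattr(r, "_3")),
            depth=int(r.depth), a=int(r.a), c=int(r.c), g=int(r.g), t=int(r.t),
            pi=None if pd.isna(r.pi) else float(r.pi),
            nonref=None if pd.isna(r.nonref) else float(r.nonref),
        ))
    return out


def write_calls(calls: Sequence[DiversificationCall], path: str | Path) -> None:
    rows = [[c.vr_id, c.metric,
             "" if c.mean_A is None else f"{c.mean_A:.10g}",
             "" if c.mean_nonA is None else f"{c.mean_nonA:.10g}",
             "" if c.sd_nonA is None else f"{c.sd_nonA:.10g}",
             "" if c.threshold is None else f"{c.threshold:.10g}",
             {True: "true", False: "false", None: "no_data"}[c.diversified],
             c.n_A_used, c.n_nonA_used, c.reason]
            for c in calls]
    pd.DataFrame(rows, columns=["vr_id", "metric", "mean_A", "mean_nonA",
                                "sd_nonA", "threshold", "diversified",
                                "n_A_used", "n_nonA_used", "reason"]
                 ).to_csv(path, sep="\t", index=False)


def write_locus_json(aggregates: Mapping[str, object], path: str | Path,
                     config_echo: Mapping | None = None) -> None:
    payload = {"aggregates": {k: v for k, v in aggregates.items()}}
    if config_echo is not None:
        payload["config"] = dict(config_echo)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
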