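"""Readers and writers for the standard formats the toolkit touches.

Coordinate conventions are converted here and only here: GFF3 is 1-based
inclusive, BED and SAM positions are handled in their native conventions,
and everything in memory is 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO

from . import seq as sequtil
from .models import AlignmentRecord, CdsFeature, GenomeRecord, MipProbe, ProbePanel


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs.

    Sequences are upper-cased and ambiguity codes collapse to N. Empty files,
    missing headers and duplicate IDs raise :class:`ParseError`.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, sequtil.normalize(str(rec.seq))))
    return records


def read_genome_fasta(path, genome_id: str | None = None) -> GenomeRecord:
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(path)))[0]
    return GenomeRecord(genome_id, dict(read_fasta(path)))


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, s in records:
            fh.write(f">{name}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (CDS rows only)


def read_gff3_cds(path) -> list[CdsFeature]:
    """Read CDS features from GFF3; 1-based inclusive -> 0-based half-open.

    Only ``type == CDS`` rows are retained. Strand is required; ``end < start``
    is a parse error. ``ID`` or ``gene_id``/``locus_tag`` attribute names the
    gene; ``product`` is carried through when present.
    """
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype != "CDS":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}: line {lineno}: end < start")
            if strand not in "+-":
                raise ParseError(f"{path}: line {lineno}: strand is required for CDS")
            attr = {}
            for pair in attrs.split(";"):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    attr[k.strip()] = v.strip()
            gene_id = attr.get("ID") or attr.get("gene_id") or attr.get("locus_tag")
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: CDS without ID attribute")
            feats.append(
                CdsFeature(
                    contig_id=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    gene_id=gene_id,
                    product=attr.get("product", ""),
                )
            )
    return feats


def write_gff3_cds(features: Iterable[CdsFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.contig_id}\ttealseq\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# SAM (minimal subset; NM tag required on mapped records)


def read_sam_min(path) -> list[AlignmentRecord]:
    """Read mapped records from a SAM file into minimal alignment records.

    Unmapped, secondary and supplementary records are skipped. A mapped
    record without an NM tag signals incompatible aligner output and raises.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                nm = rec.get_tag("NM")
            except KeyError as exc:
                raise ParseError(
                    f"{path}: mapped record {rec.query_name!r} lacks an NM tag"
                ) from exc
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    contig_id=rec.reference_name,
                    pos=rec.reference_start,
                    end=rec.reference_end,
                    mapq=rec.mapping_quality,
                    nm=int(nm),
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED6 (probe binding sites)


def probe_bed_rows(panel: ProbePanel) -> list[tuple[str, int, int, str, int, str]]:
    """BED6 rows for a panel. MIP probes emit two arm rows, ``<id>/L`` and
    ``<id>/R``, sharing the probe_id prefix. Scores carry no meaning; 0."""
    rows = []
    for probe in panel.all_probes():
        if isinstance(probe, MipProbe):
            for suffix, arm in (("/L", probe.left_arm), ("/R", probe.right_arm)):
                rows.append(
                    (arm.contig_id, arm.start, arm.end, probe.probe_id + suffix, 0, arm.strand)
                )
        else:
            rows.append(
                (probe.contig_id, probe.start, probe.end, probe.probe_id, 0, probe.strand)
            )
    return rows


def write_probe_bed(panel: ProbePanel, path) -> None:
    rows = probe_bed_rows(panel)
    if not rows:
        raise ValueError("refusing to write an empty probe BED")
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            if end < start:
                raise ParseError(f"{path}: line {lineno}: end < start")
            name = cols[3] if len(cols) > 3 else f"region{lineno}"
            score = int(float(cols[4])) if len(cols) > 4 and cols[4] != "." else 0
            strand = cols[5] if len(cols) > 5 else "+"
            rows.append((contig, start, end, name, score, strand))
    return rows


# ---------------------------------------------------------------------------
# FASTQ / tables


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, s in reads:
            fh.write(f"@{name}\n{s}\n+\n{quality_char * len(s)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def validate_file(path) -> str:
    """Best-effort format sniff + validation; returns the detected format."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".fa", ".fasta", ".fna", ".ffn"):
        read_fasta(path)
        return "fasta"
    if ext in (".gff", ".gff3"):
        read_gff3_cds(path)
        return "gff3"
    if ext == ".sam":
        read_sam_min(path)
        return "sam"
    if ext == ".bed":
        read_bed(path)
        return "bed"
    if ext in (".fq", ".fastq"):
        read_fastq(path)
        return "fastq"
    if ext in (".tsv", ".rtab", ".txt"):
        read_table(path)
        return "table"
    raise ParseError(f"unrecognized file extension: {path}")
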