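"""Read preprocessing, alignment filtering, probe counting and normalization.

Replicates the counting arithmetic of the targeted pipeline: reads are
adapter/5'-trimmed, alignments filtered on mapping quality and edit
distance (both bounds exclusive: MAPQ > 30; NM < 1 for SPE probe
alignments, NM < 3 for MIP, NM < 4 for genome alignments), counted per
probe interval with bedtools-coverage semantics (>=1 overlapping base,
half-open intervals, a read overlapping two probes increments both), and
CPM-normalized per sample and species as 1e6 * r_ijs / R_js. Genome-mode
CDS counts are summarized as RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import AlignmentRecord

BAIT_SEQ = "AGATCGGAAGAG"  # adapter bait truncating SPE/bulk reads


@dataclass(frozen=True)
class FilterPolicy:
    """Per-method alignment filter + trim rule. Bounds are exclusive."""

    method: str  # SPE | MIP | BULK_GENOME
    min_mapq: int = 30  # keep iff mapq > min_mapq
    max_nm: int = 4  # keep iff nm < max_nm
    trim_rule: str = "bait"  # "bait" | "fixed5"
    fixed_trim: int = 5
    min_read_len: int = 30

    @classmethod
    def spe(cls) -> "FilterPolicy":
        return cls(method="SPE", max_nm=1, trim_rule="bait")

    @classmethod
    def mip(cls) -> "FilterPolicy":
        return cls(method="MIP", max_nm=3, trim_rule="fixed5")

    @classmethod
    def bulk_genome(cls) -> "FilterPolicy":
        return cls(method="BULK_GENOME", max_nm=4, trim_rule="bait")

    @classmethod
    def for_method(cls, method: str) -> "FilterPolicy":
        table = {
            "SPE": cls.spe,
            "MIP": cls.mip,
            "GENOME": cls.bulk_genome,
            "BULK": cls.bulk_genome,
            "BULK_GENOME": cls.bulk_genome,
        }
        try:
            return table[method.upper()]()
        except KeyError as exc:
            raise ValueError(f"unknown method {method!r}") from exc


def trim_read(read: str, policy: FilterPolicy) -> str:
    """Apply the policy's trim rule to one read.

    SPE/bulk: truncate at the first bait occurrence through the 3' end;
    reads without the bait are unchanged. MIP: drop the first 5 bases.
    """
    if policy.trim_rule == "bait":
        i = read.find(BAIT_SEQ)
        return read if i < 0 else read[:i]
    if policy.trim_rule == "fixed5":
        return read[policy.fixed_trim :]
    raise ValueError(f"unknown trim rule {policy.trim_rule!r}")


def preprocess_reads(
    reads: list[tuple[str, str]], policy: FilterPolicy
) -> tuple[list[tuple[str, str]], int]:
    """Trim reads; drop (and count) reads shorter than min_read_len after
    trimming. Returns (kept reads, n_discarded)."""
    kept = []
    dropped = 0
    for name, s in reads:
        t = trim_read(s, policy)
        if len(t) >= policy.min_read_len:
            kept.append((name, t))
        else:
            dropped += 1
    return kept, dropped


def filter_alignments(
    records: list[AlignmentRecord], policy: FilterPolicy
) -> tuple[list[AlignmentRecord], dict]:
    """Keep records with mapq > min_mapq and nm < max_nm; tally rejections."""
    kept = []
    tally = {"kept": 0, "low_mapq": 0, "high_nm": 0}
    for r in records:
        if r.mapq <= policy.min_mapq:
            tally["low_mapq"] += 1
        elif r.nm >= policy.max_nm:
            tally["high_nm"] += 1
        else:
            kept.append(r)
            tally["kept"] += 1
    return kept, tally


def count_probe_coverage(
    records: list[AlignmentRecord],
    probe_intervals: list[tuple[str, int, int, str]],  # (probe_id, contig, start, end)
) -> tuple[dict, int]:
    """Per-probe read counts with bedtools-coverage default semantics.

    A read counts toward every probe interval it overlaps by >=1 base
    (half-open arithmetic). Returns (probe_id -> count, number of reads
    overlapping at least one probe).
    """
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for pid, contig, start, end in probe_intervals:
        by_contig.setdefault(contig, []).append((start, end, pid))
    arrays = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs])
        ends = np.array([e for _, e, _ in ivs])
        maxend = np.maximum.accumulate(ends)
        arrays[contig] = (starts, ends, maxend, [p for _, _, p in ivs])
    counts = {pid: 0 for pid, _, _, _ in probe_intervals}
    n_assigned = 0
    for r in records:
        if r.contig_id not in arrays:
            continue
        starts, ends, maxend, pids = arrays[r.contig_id]
        hi = int(np.searchsorted(starts, r.end, side="left"))
        hit_any = False
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= r.pos:
                break
            if ends[i] > r.pos:
                counts[pids[i]] += 1
                hit_any = True
        if hit_any:
            n_assigned += 1
    return counts, n_assigned


def count_matrix(
    sample_records: dict[str, list[AlignmentRecord]],
    probe_intervals: list[tuple[str, int, int, str]],
    probe_species: dict[str, str],
) -> pd.DataFrame:
    """Long-format raw count table over samples.

    Columns: probe_id, sample, species, count. Every probe appears for
    every sample (zeros included) so downstream pivots are dense.
    """
    rows = []
    for sample in sorted(sample_records):
        counts, _ = count_probe_coverage(sample_records[sample], probe_intervals)
        for pid in sorted(counts):
            rows.append(
                {
                    "probe_id": pid,
                    "sample": sample,
                    "species": probe_species.get(pid, "NA"),
                    "count": counts[pid],
                }
            )
    return pd.DataFrame(rows)


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Add a cpm column: 1e6 * r_ijs / R_js with R_js the per-sample,
    per-species total of probe counts. Species-sample groups with zero
    total get all-zero CPM and a zero_total flag."""
    df = counts.copy()
    totals = df.groupby(["sample", "species"])["count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["cpm"] = np.where(totals > 0, 1e6 * df["count"] / totals, 0.0)
    df["zero_total"] = totals == 0
    return df


def rpkm(
    cds_counts: pd.DataFrame,  # columns: gene_id, sample, count
    cds_lengths: dict[str, int],
    totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """RPKM = count / (total mapped reads / 1e6) / (CDS length / 1e3).

    ``totals`` defaults to per-sample count sums; zero totals are an error.
    """
    df = cds_counts.copy()
    if totals is None:
        totals = df.groupby("sample")["count"].sum().to_dict()
    for s, t in totals.items():
        if t <= 0:
            raise ValueError(f"sample {s!r} has zero total mapped reads")
    lengths = df["gene_id"].map(cds_lengths)
    if lengths.isna().any():
        missing = sorted(df.loc[lengths.isna(), "gene_id"].unique())
        raise ValueError(f"missing CDS lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("CDS lengths must be positive")
    tot = df["sample"].map(totals)
    df["rpkm"] = df["count"] / (tot / 1e6) / (lengths / 1e3)
    return df


def mip_arm_references(panel) -> list[tuple[str, str]]:
    """Probe binding-site reference sequences: SPE probes verbatim; MIP
    probes contribute the first and last 40 bases (the two arms) as
    separate records suffixed /L and /R."""
    from .models import MipProbe

    refs = []
    for probe in panel.all_probes():
        if isinstance(probe, MipProbe):
            refs.append((probe.probe_id + "/L", probe.left_arm.seq))
            refs.append((probe.probe_id + "/R", probe.right_arm.seq))
        else:
            refs.append((probe.probe_id, probe.seq))
    return refs


def sum_mip_arm_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse /L and /R arm rows into one probe row (counts summed)."""
    df = counts.copy()
    df["probe_id"] = df["probe_id"].str.replace(r"/[LR]$", "", regex=True)
    keys = [c for c in ("probe_id", "sample", "species") if c in df.columns]
    return df.groupby(keys, as_index=False)["count"].sum()
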