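"""Domain types shared across the toolkit.

All genomic intervals are 0-based half-open; 1-based conventions (GFF3, SAM)
are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

from . import seq as sequtil


@dataclass
class GenomeRecord:
    """A genome (or transcript set): id plus contig_id -> ACGTN sequence."""

    genome_id: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.contigs) == 0:
            raise ValueError(f"genome {self.genome_id!r} has no contigs")
        for cid, s in self.contigs.items():
            if not s:
                raise ValueError(f"contig {cid!r} of {self.genome_id!r} is empty")


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding interval on a reference contig."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid CDS interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.gene_id!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal mapped-read record: the fields the filters and counters need."""

    read_id: str
    contig_id: str
    pos: int
    end: int
    mapq: int
    nm: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.mapq <= 255):
            raise ValueError("MAPQ out of range")
        if self.nm < 0:
            raise ValueError("NM must be >= 0")
        if self.end <= self.pos:
            raise ValueError("aligned span must be non-empty")


@dataclass
class PanelConfig:
    """Tunable panel-design thresholds.

    Defaults encode the published filter set: 40-base probes, >=100-base
    spacing within a gene, homopolymer runs capped at 6, off-target exclusion
    at <=4 mismatches, host matches capped at <25 of 40 bases, and a Tm
    window trimming the distribution extremes (percentile mode) unless an
    absolute window is given.
    """

    probe_len: int = 40
    min_spacing: int = 100
    max_homopolymer: int = 6
    tm_percentile_low: float = 5.0
    tm_percentile_high: float = 95.0
    tm_low: float | None = None  # absolute-window override, degC
    tm_high: float | None = None
    inclusion_min_genomes: int = 1
    exclusion_max_mismatches: int = 4
    host_max_match_bases: int = 24
    max_probes_per_cds: int = 4
    mip_gap_len: int = 120
    mip_gap_tolerance: int = 10
    salt_mM: float = 50.0
    oligo_nM: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_len <= 0:
            raise ValueError("probe_len must be positive")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")
        if not (0 <= self.exclusion_max_mismatches < self.probe_len):
            raise ValueError("exclusion_max_mismatches must be in [0, probe_len)")

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown panel config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ProbeCandidate:
    """A 40-mer targeting unit tied to a reference window.

    ``seq`` is the probe oligo: the reference window on the + strand, or its
    reverse complement for - strand probes. ``filter_flags`` enumerates every
    composition rule the candidate violates; ``screens`` holds specificity
    verdicts keyed by screen name once computed.
    """

    probe_id: str
    species_id: str
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    seq: str
    tm: float = float("nan")
    gc_frac: float = float("nan")
    max_run: int = 0
    filter_flags: set = field(default_factory=set)
    screens: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("probe interval length must equal sequence length")

    @property
    def passes_screens(self) -> bool:
        return all(v.get("pass", False) for v in self.screens.values())


@dataclass
class MipProbe:
    """Dual-arm molecular inversion probe: two 40-mer arms flanking a gap."""

    probe_id: str
    left_arm: ProbeCandidate
    right_arm: ProbeCandidate

    def __post_init__(self) -> None:
        la, ra = self.left_arm, self.right_arm
        if la.contig_id != ra.contig_id or la.strand != ra.strand:
            raise ValueError("MIP arms must share contig and strand")
        if ra.start < la.end:
            raise ValueError("MIP arms must not overlap (left before right)")

    @property
    def gap(self) -> tuple[int, int]:
        return (self.left_arm.end, self.right_arm.start)

    @property
    def gap_len(self) -> int:
        return self.right_arm.start - self.left_arm.end

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_arm.start, self.right_arm.end)


@dataclass
class ProbePanel:
    """Accepted probe set for one species, grouped per target gene."""

    species_id: str
    architecture: str  # "SPE" | "MIP"
    probes_by_gene: dict  # gene_id -> list[ProbeCandidate] | list[MipProbe]
    config_digest: str = ""
    rejection_counts: dict = field(default_factory=dict)
    uncovered_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.architecture not in ("SPE", "MIP"):
            raise ValueError("architecture must be SPE or MIP")

    def all_probes(self) -> list:
        out = []
        for gid in sorted(self.probes_by_gene):
            out.extend(self.probes_by_gene[gid])
        return out

    @property
    def n_probes(self) -> int:
        return sum(len(v) for v in self.probes_by_gene.values())


@dataclass
class MatchHit:
    """One ungapped full-length placement of a probe on a genome."""

    genome_id: str
    contig_id: str
    pos: int
    strand: str
    mismatches: int


@dataclass
class HostMatchResult:
    """Best host-transcriptome match of a probe (max matched bases)."""

    probe_id: str
    max_match_bases: int
    transcript_id: str | None = None


def validate_probe_seq(candidate: ProbeCandidate, genome: GenomeRecord) -> bool:
    """Check that a candidate's oligo matches its reference window."""
    window = genome.contigs[candidate.contig_id][candidate.start : candidate.end]
    expect = window if candidate.strand == "+" else sequtil.revcomp(window)
    return candidate.seq == expect
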