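"""Synthetic pangenomes, expression states and probe-captured reads.

The simulator stands in for real multi-strain species data so the whole
pipeline runs at desk scale with known ground truth. It emulates:

* a species pangenome: core genes present in every strain with per-strain
  SNPs, accessory genes present in a random subset, an off-target species
  sharing a fraction of diverged homologs, and a host transcript pool;
* per-condition transcript abundances: i.i.d. log-normal baselines with a
  chosen fraction of genes multiplied by 2**(+/-log2FC) in condition B;
* probe capture: reads drawn per probe with probability proportional to
  gene abundance x probe efficiency, where SPE efficiency rises
  logistically with probe Tm and falls geometrically with each probe/
  template mismatch, while MIP efficiency is flat and tolerates up to
  three mismatches — a stylized encoding of the two chemistries' observed
  behavior. Declared, not fit.

Every function is driven by one numpy Generator; identical (config, seed)
gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seq as sequtil
from . import thermo
from .models import CdsFeature, GenomeRecord, MipProbe, PanelConfig, ProbePanel
from .quantify import BAIT_SEQ
from .targets import PresenceAbsenceMatrix


@dataclass
class SpeciesSimConfig:
    species_id: str
    n_genomes: int = 8
    n_core_genes: int = 60
    n_accessory_genes: int = 20
    gene_len_min: int = 300
    gene_len_max: int = 900
    snp_rate: float = 0.005
    accessory_presence: float = 0.5
    intergenic_len: int = 60
    gc: float = 0.33  # staphylococcal genomes are AT-rich

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate <= 1 and 0 <= self.accessory_presence <= 1):
            raise ValueError("rates must be in [0, 1]")


@dataclass
class OffTargetSimConfig:
    n_genomes: int = 2
    shared_gene_fraction: float = 0.1
    divergence: float = 0.08


@dataclass
class ExpressionSimConfig:
    mu_log: float = 2.0  # natural-log scale of the log-normal baseline
    sigma_log: float = 1.0
    de_fraction: float = 0.1
    de_log2fc: float = 3.0


@dataclass
class ReadSimConfig:
    n_reads: int = 100_000
    read_len: int = 100
    error_rate: float = 0.002
    background_fraction: float = 0.0
    method: str = "MIP"  # SPE | MIP
    strain_index: int = 1  # which strain's SNPs the sequenced sample carries
    spe_tm_slope: float = 0.3  # logistic slope per degC around the panel median
    spe_mismatch_penalty: float = 0.5  # efficiency multiplier per mismatch
    mip_mismatch_tolerance: int = 3  # mismatches tolerated at full efficiency

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate <= 1 and 0 <= self.background_fraction <= 1):
            raise ValueError("rates must be in [0, 1]")


@dataclass
class SimConfig:
    seed: int
    species: list[SpeciesSimConfig] = field(
        default_factory=lambda: [SpeciesSimConfig("Se"), SpeciesSimConfig("Sa")]
    )
    offtarget: OffTargetSimConfig = field(default_factory=OffTargetSimConfig)
    host_n_transcripts: int = 30
    host_transcript_len: int = 1500
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SpeciesTruth:
    species_id: str
    reference: GenomeRecord
    cds: list[CdsFeature]
    gene_seqs: dict  # gene_id -> reference sequence
    strains: list[GenomeRecord]
    strain_gene_seqs: list[dict]  # per strain: gene_id -> mutated seq (present genes)
    matrix: PresenceAbsenceMatrix
    cluster_to_gene: pd.DataFrame


@dataclass
class SimTruth:
    config: SimConfig
    species: dict  # species_id -> SpeciesTruth
    offtarget_genomes: list[GenomeRecord]
    host_transcripts: list[tuple[str, str]]
    abundances: pd.DataFrame | None = None  # gene_id, species, abund_A, abund_B, de_sign
    read_origins: pd.DataFrame | None = None


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at the given per-base rate (always to a different base)."""
    if rate <= 0:
        return seq
    codes = sequtil.encode(seq).copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits))
        codes[hits] = (codes[hits] + shift) % 4
    return sequtil.decode(codes)


def _simulate_species(
    cfg: SpeciesSimConfig, rng: np.random.Generator
) -> SpeciesTruth:
    n_genes = cfg.n_core_genes + cfg.n_accessory_genes
    gene_ids = [f"{cfg.species_id}_g{i:04d}" for i in range(n_genes)]
    lengths = rng.integers(cfg.gene_len_min, cfg.gene_len_max + 1, size=n_genes)
    gene_seqs = {
        gid: sequtil.random_dna(rng, int(ln), gc=cfg.gc)
        for gid, ln in zip(gene_ids, lengths)
    }
    # reference contig: genes separated by intergenic spacers
    contig_id = f"{cfg.species_id}_chr"
    pieces, cds = [], []
    pos = 0
    strands = rng.choice(list("+-"), size=n_genes)
    for gid, strand in zip(gene_ids, strands):
        spacer = sequtil.random_dna(rng, cfg.intergenic_len, gc=cfg.gc)
        pieces.append(spacer)
        pos += len(spacer)
        s = gene_seqs[gid]
        pieces.append(s)
        cds.append(
            CdsFeature(
                contig_id=contig_id,
                start=pos,
                end=pos + len(s),
                strand=str(strand),
                gene_id=gid,
            )
        )
        pos += len(s)
    reference = GenomeRecord(f"{cfg.species_id}_ref", {contig_id: "".join(pieces)})

    # presence: core in all strains, accessory in a random subset
    presence = np.ones((n_genes, cfg.n_genomes), dtype=np.int8)
    acc = np.arange(cfg.n_core_genes, n_genes)
    presence[acc] = (
        rng.random((len(acc), cfg.n_genomes)) < cfg.accessory_presence
    ).astype(np.int8)

    strains, strain_gene_seqs = [], []
    for g in range(cfg.n_genomes):
        gs = {}
        parts = []
        for gi, gid in enumerate(gene_ids):
            if presence[gi, g]:
                mut = _mutate(gene_seqs[gid], cfg.snp_rate, rng)
                gs[gid] = mut
                parts.append(mut)
                parts.append(sequtil.random_dna(rng, cfg.intergenic_len, gc=cfg.gc))
        strains.append(
            GenomeRecord(f"{cfg.species_id}_s{g:02d}", {f"{cfg.species_id}_s{g:02d}_c": "".join(parts)})
        )
        strain_gene_seqs.append(gs)
    matrix = PresenceAbsenceMatrix(
        cluster_ids=gene_ids,
        genome_ids=[s.genome_id for s in strains],
        presence=presence,
    )
    cluster_to_gene = pd.DataFrame(
        {"cluster": gene_ids, "genome": reference.genome_id, "gene_id": gene_ids}
    )
    return SpeciesTruth(
        species_id=cfg.species_id,
        reference=reference,
        cds=cds,
        gene_seqs=gene_seqs,
        strains=strains,
        strain_gene_seqs=strain_gene_seqs,
        matrix=matrix,
        cluster_to_gene=cluster_to_gene,
    )


def simulate_pangenome(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Generate target-species pangenomes, off-target genomes and host
    transcripts with full ground truth."""
    rng = rng or config.rng()
    species = {}
    for scfg in config.species:
        species[scfg.species_id] = _simulate_species(scfg, rng)

    # off-target genomes: shared diverged homologs + private sequence
    off = []
    ot = config.offtarget
    shared_pool = []
    for sid in sorted(species):
        st = species[sid]
        prev = st.matrix.prevalence()
        core_ids = [c for c in st.matrix.cluster_ids if prev[c] == st.matrix.n_genomes]
        n_shared = int(round(ot.shared_gene_fraction * len(core_ids)))
        shared_pool.extend(st.gene_seqs[g] for g in core_ids[:n_shared])
    for i in range(ot.n_genomes):
        parts = []
        for s in shared_pool:
            parts.append(_mutate(s, ot.divergence, rng))
            parts.append(sequtil.random_dna(rng, 50, gc=0.33))
        parts.append(sequtil.random_dna(rng, 20_000, gc=0.33))
        off.append(GenomeRecord(f"offtarget_{i:02d}", {f"off{i:02d}_c": "".join(parts)}))

    host = [
        (f"host_tx{i:04d}", sequtil.random_dna(rng, config.host_transcript_len, gc=0.45))
        for i in range(config.host_n_transcripts)
    ]
    return SimTruth(
        config=config, species=species, offtarget_genomes=off, host_transcripts=host
    )


def simulate_expression(
    truth: SimTruth, config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-condition transcript abundances with planted DE genes.

    Baselines are i.i.d. log-normal(mu, sigma); a ``de_fraction`` of genes
    (random signs) is multiplied by 2**(+/-log2FC) in condition B, all
    other genes are identical across conditions.
    """
    config = config or truth.config
    rng = rng or np.random.default_rng(config.seed + 1)
    e = config.expression
    frames = []
    for sid in sorted(truth.species):
        st = truth.species[sid]
        gene_ids = list(st.gene_seqs)
        base = rng.lognormal(e.mu_log, e.sigma_log, size=len(gene_ids))
        n_de = int(round(e.de_fraction * len(gene_ids)))
        de_idx = rng.choice(len(gene_ids), size=n_de, replace=False)
        signs = np.zeros(len(gene_ids), dtype=int)
        signs[de_idx] = rng.choice([-1, 1], size=n_de)
        abund_b = base * np.power(2.0, signs * e.de_log2fc)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "species": sid,
                    "abund_A": base,
                    "abund_B": abund_b,
                    "de_sign": signs,
                }
            )
        )
    truth.abundances = pd.concat(frames, ignore_index=True)
    return truth.abundances


# ---------------------------------------------------------------------------
# read simulation


def _probe_rows(panel: ProbePanel) -> list[dict]:
    """Flatten a panel into per-probe rows with span, strand, Tm, oligo parts."""
    rows = []
    for probe in panel.all_probes():
        if isinstance(probe, MipProbe):
            rows.append(
                {
                    "probe_id": probe.probe_id,
                    "species": panel.species_id,
                    "gene_id": probe.left_arm.gene_id,
                    "contig_id": probe.left_arm.contig_id,
                    "start": probe.left_arm.start,
                    "end": probe.right_arm.end,
                    "strand": probe.left_arm.strand,
                    "tm": 0.5 * (probe.left_arm.tm + probe.right_arm.tm),
                    "arm_intervals": [
                        (probe.left_arm.start, probe.left_arm.end),
                        (probe.right_arm.start, probe.right_arm.end),
                    ],
                    "arm_seqs": [probe.left_arm.seq, probe.right_arm.seq],
                    "arm_strand": probe.left_arm.strand,
                }
            )
        else:
            rows.append(
                {
                    "probe_id": probe.probe_id,
                    "species": panel.species_id,
                    "gene_id": probe.gene_id,
                    "contig_id": probe.contig_id,
                    "start": probe.start,
                    "end": probe.end,
                    "strand": probe.strand,
                    "tm": probe.tm,
                    "arm_intervals": [(probe.start, probe.end)],
                    "arm_seqs": [probe.seq],
                    "arm_strand": probe.strand,
                }
            )
    return rows


def _template_contigs(st: SpeciesTruth, strain_index: int) -> tuple[dict, set]:
    """Sequenced-sample template: reference coordinates with the chosen
    strain's SNPs patched in gene by gene. Genes absent from the strain
    keep reference sequence but are reported for zero-weighting."""
    strain_genes = st.strain_gene_seqs[strain_index]
    contig_id = next(iter(st.reference.contigs))
    arr = list(st.reference.contigs[contig_id])
    absent = set()
    for f in st.cds:
        if f.gene_id in strain_genes:
            arr[f.start : f.end] = strain_genes[f.gene_id]
        else:
            absent.add(f.gene_id)
    return {contig_id: "".join(arr)}, absent


def probe_efficiencies(
    rows: list[dict], templates: dict, cfg: ReadSimConfig
) -> np.ndarray:
    """Per-probe capture efficiency under the stylized chemistry model.

    SPE: logistic in (Tm - panel median Tm) times penalty**mismatches.
    MIP: flat, full efficiency up to the mismatch tolerance, zero above.
    Mismatches are counted probe-vs-template over the arm windows.
    """
    tms = np.array([r["tm"] for r in rows])
    med = float(np.median(tms)) if len(tms) else 0.0
    eff = np.zeros(len(rows))
    for i, r in enumerate(rows):
        template = templates[r["contig_id"]]
        mm = 0
        for (a, b), oligo in zip(r["arm_intervals"], r["arm_seqs"]):
            window = template[a:b]
            ref_oligo = window if r["arm_strand"] == "+" else sequtil.revcomp(window)
            mm += sequtil.hamming(oligo, ref_oligo)
        if cfg.method == "SPE":
            base = 1.0 / (1.0 + np.exp(-cfg.spe_tm_slope * (tms[i] - med)))
            eff[i] = base * (cfg.spe_mismatch_penalty**mm)
        else:
            eff[i] = 1.0 if mm <= cfg.mip_mismatch_tolerance else 0.0
    return eff


def simulate_captured_reads(
    panels: list[ProbePanel],
    truth: SimTruth,
    abundance_col: str = "abund_A",
    rng: np.random.Generator | None = None,
    config: SimConfig | None = None,
) -> dict:
    """Draw probe-captured reads plus host background with full truth.

    Returns a dict with ``fastq`` [(read_id, seq)], ``sam`` (text lines of
    the truth alignment against the reference genomes, NM exact),
    ``origins`` (DataFrame read_id/origin/species/gene), and the per-probe
    expected weights. Reads are emitted probe-major then background; the
    origin table partitions all reads.
    """
    config = config or truth.config
    cfg = config.reads
    rng = rng or np.random.default_rng(config.seed + 2)
    abund = truth.abundances
    if abund is None:
        raise ValueError("simulate_expression must run before read simulation")
    abund_map = dict(zip(zip(abund["species"], abund["gene_id"]), abund[abundance_col]))

    rows = []
    templates = {}
    absent_genes = set()
    for panel in panels:
        st = truth.species[panel.species_id]
        tmpl, absent = _template_contigs(st, cfg.strain_index)
        templates.update(tmpl)
        absent_genes |= {(panel.species_id, g) for g in absent}
        rows.extend(_probe_rows(panel))
    eff = probe_efficiencies(rows, templates, cfg)
    weights = np.array(
        [
            0.0
            if (r["species"], r["gene_id"]) in absent_genes
            else abund_map.get((r["species"], r["gene_id"]), 0.0)
            for r in rows
        ]
    )
    weights = weights * eff
    if weights.sum() <= 0:
        raise ValueError("no probe has positive capture weight")
    probs = weights / weights.sum()

    n_bg = int(round(cfg.background_fraction * cfg.n_reads))
    n_on = cfg.n_reads - n_bg
    per_probe = rng.multinomial(n_on, probs)

    ref_contigs = {}
    for st in truth.species.values():
        ref_contigs.update(st.reference.contigs)

    fastq, sam, origins = [], [], []
    sq_lines = [
        f"@SQ\tSN:{cid}\tLN:{len(s)}"
        for cid, s in sorted(ref_contigs.items())
    ]
    sam.append("@HD\tVN:1.6\tSO:unsorted")
    sam.extend(sq_lines)
    sam.append(f"@CO\ttealseq-simulator seed={config.seed}")
    ridx = 0
    for r, n in zip(rows, per_probe):
        if n == 0:
            continue
        template = templates[r["contig_id"]]
        reference = ref_contigs[r["contig_id"]]
        for _ in range(int(n)):
            ridx += 1
            rid = f"r{ridx:07d}"
            fastq_seq, rec = _one_read(rid, r, template, reference, cfg, rng)
            fastq.append((rid, fastq_seq))
            sam.append(rec)
            origins.append(
                {
                    "read_id": rid,
                    "origin": r["probe_id"],
                    "species": r["species"],
                    "gene_id": r["gene_id"],
                }
            )
    host = truth.host_transcripts
    for _ in range(n_bg):
        ridx += 1
        rid = f"r{ridx:07d}"
        ti = int(rng.integers(0, len(host)))
        name, s = host[ti]
        start = int(rng.integers(0, max(1, len(s) - cfg.read_len + 1)))
        seq = _mutate(s[start : start + cfg.read_len], cfg.error_rate, rng)
        if cfg.method == "MIP":
            seq = sequtil.random_dna(rng, 5) + seq
        fastq.append((rid, seq))
        sam.append(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{'I' * len(seq)}")
        origins.append(
            {"read_id": rid, "origin": "background", "species": "host", "gene_id": name}
        )
    return {
        "fastq": fastq,
        "sam": sam,
        "origins": pd.DataFrame(origins),
        "probe_rows": rows,
        "weights": weights,
        "efficiencies": eff,
        "n_background": n_bg,
    }


def _one_read(
    rid: str,
    row: dict,
    template: str,
    reference: str,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """One captured read: FASTQ sequence (with chemistry artifacts) and the
    truth SAM record of its trimmed alignment to the reference genome."""
    L = cfg.read_len
    if row["strand"] == "+":
        w_start = row["start"]
        w_end = min(w_start + L, len(template))
    else:
        w_end = row["end"]
        w_start = max(w_end - L, 0)
    window = _mutate(template[w_start:w_end], cfg.error_rate, rng)
    aligned = window  # reference-orientation aligned portion
    pad = ""
    if len(window) < L:
        # template runs out: the library reads through into adapter
        pad = (BAIT_SEQ + "A" * L)[: L - len(window)]
    if row["strand"] == "+":
        fastq_seq = window + pad
    else:
        fastq_seq = sequtil.revcomp(window) + pad
    if cfg.method == "MIP":
        fastq_seq = sequtil.random_dna(rng, 5) + fastq_seq
    nm = sequtil.hamming(aligned, reference[w_start:w_end])
    flag = 0 if row["strand"] == "+" else 16
    rec = (
        f"{rid}\t{flag}\t{row['contig_id']}\t{w_start + 1}\t60\t{len(aligned)}M\t*\t0\t0\t"
        f"{aligned}\t{'I' * len(aligned)}\tNM:i:{nm}"
    )
    return fastq_seq, rec


def uniform_probe_panel(
    st: SpeciesTruth,
    probes_per_gene: int = 3,
    config: PanelConfig | None = None,
) -> ProbePanel:
    """An idealized SPE probe set: evenly spaced + strand probes on every
    gene, no specificity screening. Useful for experiments that exercise
    quantification/DE machinery independent of panel-design outcomes."""
    config = config or PanelConfig()
    L = config.probe_len
    probes_by_gene = {}
    from .models import ProbeCandidate

    for f in st.cds:
        span = len(f) - L
        if span < 0:
            continue
        k = max(1, probes_per_gene)
        offsets = sorted({int(round(i * span / max(k - 1, 1))) for i in range(k)})
        cands = []
        contig = st.reference.contigs[f.contig_id]
        for off in offsets:
            start = f.start + off
            oligo = contig[start : start + L]
            if "N" in oligo:
                continue
            cands.append(
                ProbeCandidate(
                    probe_id=f"{st.species_id}|{f.gene_id}|{start}+",
                    species_id=st.species_id,
                    gene_id=f.gene_id,
                    contig_id=f.contig_id,
                    start=start,
                    end=start + L,
                    strand="+",
                    seq=oligo,
                )
            )
        if cands:
            tms = thermo.melting_temperatures(
                np.stack([sequtil.encode(c.seq) for c in cands])
            )
            for c, tm in zip(cands, tms):
                c.tm = float(tm)
            probes_by_gene[f.gene_id] = cands
    return ProbePanel(
        species_id=st.species_id,
        architecture="SPE",
        probes_by_gene=probes_by_gene,
        config_digest=config.digest(),
    )


def simulate_count_matrix(
    panels: list[ProbePanel],
    truth: SimTruth,
    n_per_condition: int = 3,
    depth: int = 100_000,
    replicate_sigma: float = 0.15,
    rng: np.random.Generator | None = None,
    config: SimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Probe-level count matrix over a two-condition experiment.

    A multinomial draw of ``depth`` reads per sample with per-probe weights
    abundance x efficiency x per-sample log-normal replicate noise. Returns
    (counts probes x samples, sample sheet, probe -> gene map).
    """
    config = config or truth.config
    cfg = config.reads
    rng = rng or np.random.default_rng(config.seed + 3)
    abund = truth.abundances
    if abund is None:
        raise ValueError("simulate_expression must run before count simulation")

    rows, templates = [], {}
    for panel in panels:
        st = truth.species[panel.species_id]
        tmpl, _ = _template_contigs(st, cfg.strain_index)
        templates.update(tmpl)
        rows.extend(_probe_rows(panel))
    eff = probe_efficiencies(rows, templates, cfg)
    probe_ids = [r["probe_id"] for r in rows]
    gene_of_probe = pd.Series([r["gene_id"] for r in rows], index=probe_ids)

    counts = {}
    sheet = []
    for cond, col in (("A", "abund_A"), ("B", "abund_B")):
        amap = dict(zip(zip(abund["species"], abund["gene_id"]), abund[col]))
        base = np.array([amap.get((r["species"], r["gene_id"]), 0.0) for r in rows]) * eff
        for rep in range(n_per_condition):
            sample = f"{cond}{rep + 1}"
            noise = rng.lognormal(0.0, replicate_sigma, size=len(rows))
            w = base * noise
            counts[sample] = rng.multinomial(depth, w / w.sum())
            sheet.append({"sample": sample, "condition": cond})
    counts_df = pd.DataFrame(counts, index=probe_ids)
    return counts_df, pd.DataFrame(sheet), gene_of_probe
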