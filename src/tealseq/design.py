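"""Candidate probe generation, scoring, filtering and panel assembly.

The designable unit is a 40-mer window on a target CDS, tiled at step 1 on
both strands (capture templates are double-stranded after second-strand
cDNA synthesis). Candidates are scored thermodynamically (nearest-neighbor
Tm) and compositionally, filtered, and assembled into a panel under a
minimum within-gene spacing (default 100 bases between probe starts) and a
per-gene probe budget.

Spacing selection is cardinality-optimal: picking the maximum number of
points with pairwise distance >= d is the classic activity-selection
problem, for which the left-to-right greedy sweep is exact. MIP arm pairing
additionally has to respect arm re-use and a target gap length; it is
solved by an exact dynamic program over arms ordered by start coordinate.
"""

from __future__ import annotations

import numpy as np

from . import seq as sequtil
from . import thermo
from .models import CdsFeature, GenomeRecord, MipProbe, PanelConfig, ProbeCandidate, ProbePanel


def tile_candidates(
    cds: CdsFeature,
    genome: GenomeRecord,
    config: PanelConfig,
    species_id: str = "",
) -> list[ProbeCandidate]:
    """One candidate per start offset per strand over the CDS (step 1).

    Windows containing N are excluded (probes are synthesized oligos and
    must be fully specified). A CDS shorter than probe_len yields an empty
    list. Tm, GC and homopolymer metrics are filled in batch.
    """
    L = config.probe_len
    contig = genome.contigs[cds.contig_id]
    if len(cds) < L:
        return []
    out = []
    windows = []
    for start in range(cds.start, cds.end - L + 1):
        window = contig[start : start + L]
        if "N" in window:
            continue
        for strand in "+-":
            oligo = window if strand == "+" else sequtil.revcomp(window)
            out.append(
                ProbeCandidate(
                    probe_id=f"{species_id or 'sp'}|{cds.gene_id}|{start}{strand}",
                    species_id=species_id,
                    gene_id=cds.gene_id,
                    contig_id=cds.contig_id,
                    start=start,
                    end=start + L,
                    strand=strand,
                    seq=oligo,
                    gc_frac=sequtil.gc_fraction(oligo),
                    max_run=sequtil.max_homopolymer_run(oligo),
                )
            )
            windows.append(sequtil.encode(oligo))
    if out:
        tms = thermo.melting_temperatures(
            np.stack(windows), salt_mM=config.salt_mM, oligo_nM=config.oligo_nM
        )
        for cand, tm in zip(out, tms):
            cand.tm = float(tm)
    return out


def tm_window(candidates: list[ProbeCandidate], config: PanelConfig) -> tuple[float, float]:
    """Tm acceptance window: absolute override, or percentile trimming of
    the candidate Tm distribution ("extremes of melting temperature")."""
    if config.tm_low is not None and config.tm_high is not None:
        return (config.tm_low, config.tm_high)
    if not candidates:
        return (-np.inf, np.inf)
    tms = np.array([c.tm for c in candidates])
    lo = float(np.percentile(tms, config.tm_percentile_low))
    hi = float(np.percentile(tms, config.tm_percentile_high))
    return (lo, hi)


def composition_filter(
    candidate: ProbeCandidate, config: PanelConfig, window: tuple[float, float]
) -> set[str]:
    """All violated composition rules (empty set = pass).

    Rules: homopolymer runs of more than ``max_homopolymer`` (default:
    no runs of >6 of a single base) and Tm outside the window. The boundary
    run of exactly 6 passes.
    """
    reasons = set()
    if candidate.max_run > config.max_homopolymer:
        reasons.add("homopolymer")
    lo, hi = window
    if not np.isfinite(candidate.tm):
        reasons.add("tm_undefined")
    elif candidate.tm < lo:
        reasons.add("tm_low")
    elif candidate.tm > hi:
        reasons.add("tm_high")
    candidate.filter_flags |= reasons
    return reasons


def select_spaced(starts: list[int], min_spacing: int) -> list[int]:
    """Indices of a maximum-cardinality subset with pairwise start distance
    >= min_spacing. ``starts`` must be sorted ascending. Greedy left-to-right
    is exact for this objective; ties (equal starts) keep the first, which
    upstream ordering makes the + strand candidate."""
    chosen = []
    last = None
    for i, s in enumerate(starts):
        if last is None or s - last >= min_spacing:
            chosen.append(i)
            last = s
    return chosen


def _tm_centrality_order(
    cands: list[ProbeCandidate], center: float | None = None
) -> list[ProbeCandidate]:
    if center is None:
        center = float(np.median([c.tm for c in cands]))
    return sorted(
        cands, key=lambda c: (abs(c.tm - center), c.start, 0 if c.strand == "+" else 1)
    )


def assemble_panel(
    candidates: list[ProbeCandidate],
    config: PanelConfig,
    species_id: str = "",
    target_genes: list[str] | None = None,
    tm_center: float | None = None,
) -> ProbePanel:
    """Assemble an SPE panel from fully filtered/screened candidates.

    Per gene: maximum-cardinality spacing selection, then the per-gene
    budget keeps the probes with Tm closest to the gene-set median
    (tie-break: smaller start, then + strand). Genes with no passing
    candidate are listed as uncovered.
    """
    passing = [c for c in candidates if not c.filter_flags and c.passes_screens]
    by_gene: dict[str, list[ProbeCandidate]] = {}
    for c in passing:
        by_gene.setdefault(c.gene_id, []).append(c)
    if tm_center is None and passing:
        tm_center = float(np.median([c.tm for c in passing]))
    probes_by_gene = {}
    for gid in sorted(by_gene):
        cands = sorted(by_gene[gid], key=lambda c: (c.start, 0 if c.strand == "+" else 1))
        idx = select_spaced([c.start for c in cands], config.min_spacing)
        chosen = [cands[i] for i in idx]
        if len(chosen) > config.max_probes_per_cds:
            chosen = _tm_centrality_order(chosen, tm_center)[: config.max_probes_per_cds]
            chosen.sort(key=lambda c: c.start)
        probes_by_gene[gid] = chosen
    genes = target_genes if target_genes is not None else sorted(by_gene)
    uncovered = [g for g in genes if not probes_by_gene.get(g)]
    return ProbePanel(
        species_id=species_id,
        architecture="SPE",
        probes_by_gene=probes_by_gene,
        config_digest=config.digest(),
        uncovered_genes=uncovered,
    )


def pair_mip_arms(
    arms: list[ProbeCandidate], config: PanelConfig
) -> list[tuple[ProbeCandidate, ProbeCandidate]]:
    """Exact maximum-cardinality MIP pairing on one contig+strand.

    Constraints: gap length (right.start - left.end) within
    mip_gap_len +/- tolerance; each arm used at most once; left-arm starts
    of distinct MIPs >= min_spacing apart. Solved by a DP over arms sorted
    by start: because the gap plus arm length exceeds the spacing under any
    sane geometry, the only forward conflict a selection creates is its own
    right arm, which is carried in the DP state.
    """
    arms = sorted(arms, key=lambda c: (c.start, 0 if c.strand == "+" else 1))
    n = len(arms)
    starts = [a.start for a in arms]
    lo = config.mip_gap_len - config.mip_gap_tolerance
    hi = config.mip_gap_len + config.mip_gap_tolerance
    rights = []  # feasible right-arm indices per left index
    for i, a in enumerate(arms):
        lo_s, hi_s = max(a.end, a.end + lo), a.end + hi
        js = [j for j in range(n) if j != i and lo_s <= arms[j].start <= hi_s]
        rights.append(js)

    # The single-carry DP below assumes a previous MIP can interfere with at
    # most one future selection (via its own right arm). That holds when the
    # probe+gap span stays under twice the spacing and the spacing exceeds
    # twice the gap tolerance; otherwise fall back to exhaustive search.
    span_ok = (
        config.probe_len + hi < 2 * config.min_spacing
        and config.min_spacing > 2 * config.mip_gap_tolerance
    )
    if not span_ok:
        return _pair_mip_exhaustive(arms, rights, starts, config)

    from functools import lru_cache
    import bisect
    import sys

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 3 * n + 100))

    @lru_cache(maxsize=None)
    def f(i: int, forb: int) -> tuple[int, tuple]:
        if i >= n:
            return (0, ())
        if forb >= 0 and forb < i:
            forb = -1
        best = f(i + 1, forb)
        if i != forb:
            jump_pos = starts[i] + config.min_spacing
            j0 = bisect.bisect_left(starts, jump_pos)
            for r in rights[i]:
                if r == forb:
                    continue
                carry = r if r >= j0 else -1
                cnt, rest = f(j0, carry)
                cand = (1 + cnt, ((i, r),) + rest)
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
        return best

    _, pairs = f(0, -1)
    f.cache_clear()
    return [(arms[i], arms[r]) for i, r in pairs]


def _pair_mip_exhaustive(arms, rights, starts, config):
    """Exhaustive maximum pairing for degenerate geometries (small n only)."""
    n = len(arms)
    if n > 22:
        raise ValueError(
            "MIP pairing with this gap/spacing geometry requires exhaustive "
            f"search, which is infeasible for {n} arms; tighten the geometry"
        )
    best: tuple[int, tuple] = (0, ())

    def rec(i: int, used: frozenset, last_left: int | None, acc: tuple):
        nonlocal best
        if len(acc) > best[0] or (len(acc) == best[0] and acc < best[1]):
            best = (len(acc), acc)
        if i >= n:
            return
        rec(i + 1, used, last_left, acc)
        if i in used:
            return
        if last_left is not None and starts[i] - starts[last_left] < config.min_spacing:
            return
        for r in rights[i]:
            if r not in used:
                rec(i + 1, used | {i, r}, i, acc + ((i, r),))

    rec(0, frozenset(), None, ())
    return [(arms[i], arms[r]) for i, r in best[1]]


def design_mip(
    candidates: list[ProbeCandidate],
    config: PanelConfig,
    species_id: str = "",
    target_genes: list[str] | None = None,
) -> ProbePanel:
    """Assemble a MIP panel from fully filtered/screened arm candidates.

    Arms are paired per gene, contig and strand; genes with no feasible
    pairing are reported as uncovered. The per-gene budget keeps the
    left-most MIPs.
    """
    passing = [c for c in candidates if not c.filter_flags and c.passes_screens]
    by_key: dict[tuple[str, str, str], list[ProbeCandidate]] = {}
    for c in passing:
        by_key.setdefault((c.gene_id, c.contig_id, c.strand), []).append(c)
    probes_by_gene: dict[str, list[MipProbe]] = {}
    for gid, cid, strand in sorted(by_key):
        pairs = pair_mip_arms(by_key[(gid, cid, strand)], config)
        mips = probes_by_gene.setdefault(gid, [])
        for left, right in pairs:
            pid = f"{species_id or 'sp'}|{gid}|mip{left.start}{strand}"
            mips.append(MipProbe(probe_id=pid, left_arm=left, right_arm=right))
    for gid in list(probes_by_gene):
        mips = sorted(probes_by_gene[gid], key=lambda m: m.left_arm.start)
        probes_by_gene[gid] = mips[: config.max_probes_per_cds]
    genes = target_genes if target_genes is not None else sorted(probes_by_gene)
    uncovered = [g for g in genes if not probes_by_gene.get(g)]
    return ProbePanel(
        species_id=species_id,
        architecture="MIP",
        probes_by_gene={g: v for g, v in probes_by_gene.items() if v},
        config_digest=config.digest(),
        uncovered_genes=uncovered,
    )


def panel_summary(panel: ProbePanel, n_target_genes: int | None = None) -> dict:
    """Probes-per-gene histogram and coverage fraction (genes with >=1
    probe over the number of target genes)."""
    counts = {g: len(v) for g, v in panel.probes_by_gene.items() if v}
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    if n_target_genes is None:
        n_target_genes = len(counts) + len(panel.uncovered_genes)
    coverage = len(counts) / n_target_genes if n_target_genes else 0.0
    return {
        "n_probes": panel.n_probes,
        "n_genes_covered": len(counts),
        "n_target_genes": n_target_genes,
        "probes_per_gene_hist": dict(sorted(hist.items())),
        "coverage": coverage,
    }
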