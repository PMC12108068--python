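"""End-to-end panel design: tiling -> scoring -> screening -> assembly.

Ties the design and specificity modules together for one species. The
specificity screens dominate the cost of panel design, so they are
evaluated lazily in greedy scan order: a candidate is screened only when
the spacing sweep is about to accept it. For SPE this selects exactly the
greedy (and therefore maximum-cardinality) solution over the set of
passing candidates, at a fraction of the screening cost; for MIP a greedy
arm pairing is used here while :func:`tealseq.design.design_mip` remains
the exact optimizer for pre-screened candidate lists.
"""

from __future__ import annotations

import numpy as np

from . import design as pdesign
from . import specificity as spec
from .models import CdsFeature, GenomeRecord, MipProbe, PanelConfig, ProbePanel


def _screen(cand, target_index, offtarget_index, host_index, config) -> bool:
    cand.screens = spec.screen_probe(
        cand.seq,
        target_index,
        offtarget_index,
        host_index,
        min_genomes=config.inclusion_min_genomes,
        exclusion_max_mismatches=config.exclusion_max_mismatches,
        host_max_match_bases=config.host_max_match_bases,
        probe_id=cand.probe_id,
        short_circuit=True,
    )
    return cand.passes_screens and len(cand.screens) == 3


def design_panel(
    reference: GenomeRecord,
    cds_features: list[CdsFeature],
    config: PanelConfig,
    architecture: str,
    species_id: str,
    inclusion_genomes: list[GenomeRecord],
    offtarget_genomes: list[GenomeRecord] | None = None,
    host_transcripts: list[tuple[str, str]] | None = None,
    seed_k: int = 8,
) -> ProbePanel:
    """Design an SPE or MIP panel for one species.

    ``inclusion_genomes`` are the target-species strains the inclusion
    screen counts perfect matches in; ``offtarget_genomes`` feed the
    exclusion screen; ``host_transcripts`` the host screen.
    """
    if architecture not in ("SPE", "MIP"):
        raise ValueError("architecture must be SPE or MIP")
    # the inclusion screen only needs perfect matches, so a long seed is
    # pigeonhole-valid and keeps spurious verification candidates rare
    inclusion_k = min(16, config.probe_len)
    target_index = spec.GenomeIndex(inclusion_genomes, k=inclusion_k)
    offtarget_index = (
        spec.GenomeIndex(offtarget_genomes, k=seed_k) if offtarget_genomes else None
    )
    host_index = (
        spec.HostIndex(host_transcripts, probe_len=config.probe_len)
        if host_transcripts
        else None
    )

    by_gene: dict[str, list] = {}
    all_cands = []
    for f in sorted(cds_features, key=lambda f: (f.contig_id, f.start, f.gene_id)):
        cands = pdesign.tile_candidates(f, reference, config, species_id=species_id)
        by_gene.setdefault(f.gene_id, []).extend(cands)
        all_cands.extend(cands)
    window = pdesign.tm_window(all_cands, config)
    tm_center = float(np.median([c.tm for c in all_cands])) if all_cands else 0.0
    rejections = {"homopolymer": 0, "tm": 0, "inclusion": 0, "exclusion": 0, "host": 0}

    def comp_ok(c) -> bool:
        reasons = pdesign.composition_filter(c, config, window)
        if "homopolymer" in reasons:
            rejections["homopolymer"] += 1
        if reasons & {"tm_low", "tm_high", "tm_undefined"}:
            rejections["tm"] += 1
        return not reasons

    def screen_ok(c) -> bool:
        ok = _screen(c, target_index, offtarget_index, host_index, config)
        if not ok:
            for name, v in c.screens.items():
                if not v["pass"]:
                    rejections[name] += 1
        return ok

    probes_by_gene: dict[str, list] = {}
    uncovered: list[str] = []
    for gid in sorted(by_gene):
        cands = sorted(by_gene[gid], key=lambda c: (c.start, 0 if c.strand == "+" else 1))
        if architecture == "SPE":
            chosen = _greedy_spe(cands, config, comp_ok, screen_ok)
            if len(chosen) > config.max_probes_per_cds:
                chosen = sorted(
                    chosen,
                    key=lambda c: (abs(c.tm - tm_center), c.start, 0 if c.strand == "+" else 1),
                )[: config.max_probes_per_cds]
                chosen.sort(key=lambda c: (c.start, c.strand))
        else:
            chosen = _greedy_mip(cands, config, species_id, gid, comp_ok, screen_ok)
        if chosen:
            probes_by_gene[gid] = chosen
        else:
            uncovered.append(gid)
    return ProbePanel(
        species_id=species_id,
        architecture=architecture,
        probes_by_gene=probes_by_gene,
        config_digest=config.digest(),
        rejection_counts=rejections,
        uncovered_genes=uncovered,
    )


def _greedy_spe(cands, config, comp_ok, screen_ok):
    chosen = []
    last = None
    for c in cands:
        if last is not None and c.start - last < config.min_spacing:
            continue
        if not comp_ok(c):
            continue
        if not screen_ok(c):
            continue
        chosen.append(c)
        last = c.start
    return chosen


def _greedy_mip(cands, config, species_id, gene_id, comp_ok, screen_ok):
    """Greedy arm pairing with lazy screening.

    Lefts are scanned in coordinate order; for each accepted left arm the
    right-arm window (gap length +/- tolerance, same strand) is scanned for
    the first passing unused arm. Verdict caches avoid re-screening.
    """
    import bisect

    lo = config.mip_gap_len - config.mip_gap_tolerance
    hi = config.mip_gap_len + config.mip_gap_tolerance
    starts = [c.start for c in cands]
    status: dict[str, bool] = {}  # probe_id -> passes comp+screens

    def ok(c) -> bool:
        if c.probe_id not in status:
            status[c.probe_id] = bool(comp_ok(c)) and screen_ok(c)
        return status[c.probe_id]

    used: set[str] = set()
    mips = []
    last_left = None
    for i, c in enumerate(cands):
        if len(mips) >= config.max_probes_per_cds:
            break
        if c.probe_id in used:
            continue
        if last_left is not None and c.start - last_left < config.min_spacing:
            continue
        lo_s, hi_s = max(c.end, c.end + lo), c.end + hi
        j0 = bisect.bisect_left(starts, lo_s, lo=i + 1)
        j1 = bisect.bisect_right(starts, hi_s, lo=j0)
        window_cands = [
            d
            for d in cands[j0:j1]
            if d.strand == c.strand and d.probe_id not in used
        ]
        if not window_cands:  # no feasible right arm: skip before screening
            continue
        if not ok(c):
            continue
        partner = None
        for d in window_cands:
            if ok(d):
                partner = d
                break
        if partner is None:
            continue
        pid = f"{species_id or 'sp'}|{gene_id}|mip{c.start}{c.strand}"
        mips.append(MipProbe(probe_id=pid, left_arm=c, right_arm=partner))
        used.add(c.probe_id)
        used.add(partner.probe_id)
        last_left = c.start
    return mips
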