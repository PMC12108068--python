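"""Mismatch-tolerant specificity screening of probe oligos.

Three screens gate a candidate probe:

* inclusion  — a perfect (0-mismatch) match in at least ``min_genomes`` of
  the target-species genomes, so the probe tolerates within-species
  strain variation;
* exclusion  — no ungapped full-length placement with <=4 mismatches on any
  off-target genome ("fewer than five mismatches" excluded);
* host       — fewer than 25 of 40 bases matching any host transcript,
  measured as the maximum matched-base count over every ungapped
  alignment diagonal on either strand.

Hit search is seed-and-verify with a pigeonhole guarantee: splitting a
probe of length L into m+1 disjoint seeds of length k = floor(L/(m+1))
means any placement with <=m mismatches contains at least one exact seed,
so the search is complete, not heuristic. The host screen is an exact
vectorized all-diagonal scan (no seeding), so its result always equals the
brute-force dynamic-programming value.
"""

from __future__ import annotations

import numpy as np

from . import seq as sequtil
from .models import GenomeRecord, HostMatchResult, MatchHit

HIT_CAP_PER_GENOME = 1000  # bound pathological low-complexity probes


class GenomeIndex:
    """k-mer seed index over a set of genomes (forward strands).

    Strand search happens on the probe side: a probe and its reverse
    complement are both queried, so indexing one strand suffices.
    """

    def __init__(self, genomes: list[GenomeRecord], k: int = 8):
        if k < 1 or k > 31:
            raise ValueError("seed length k must be in [1, 31]")
        self.k = k
        self.genomes = list(genomes)
        self._contigs: list[tuple[str, str, np.ndarray]] = []  # (genome, contig, codes)
        index: dict[int, list] = {}
        for g in self.genomes:
            for cid in sorted(g.contigs):
                codes = sequtil.encode(g.contigs[cid])
                ci = len(self._contigs)
                self._contigs.append((g.genome_id, cid, codes))
                for key, pos in _kmer_keys(codes, k):
                    index.setdefault(key, []).append((ci, pos))
        self._index = {key: np.asarray(v, dtype=np.int64) for key, v in index.items()}

    def seed_positions(self, key: int) -> np.ndarray:
        return self._index.get(key, np.empty((0, 2), dtype=np.int64)).reshape(-1, 2)

    def contig(self, ci: int) -> tuple[str, str, np.ndarray]:
        return self._contigs[ci]


def _kmer_keys(codes: np.ndarray, k: int):
    """Yield (base-4 key, position) for every fully specified k-mer."""
    n = len(codes)
    if n < k:
        return
    valid = codes < 4
    ok = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        ok &= valid[off : off + n - k + 1]
    keys = np.zeros(n - k + 1, dtype=np.int64)
    for off in range(k):
        keys = keys * 4 + codes[off : off + n - k + 1]
    for pos in np.flatnonzero(ok):
        yield int(keys[pos]), int(pos)


def _probe_keys(codes: np.ndarray, k: int, n_seeds: int) -> list[tuple[int, int]]:
    """Disjoint seed (key, offset) pairs for the pigeonhole query."""
    out = []
    for i in range(n_seeds):
        off = i * k
        sub = codes[off : off + k]
        key = 0
        for c in sub:
            key = key * 4 + int(c)
        out.append((key, off))
    return out


def find_hits(
    probe_seq: str,
    index: GenomeIndex,
    max_mismatches: int,
    cap_per_genome: int = HIT_CAP_PER_GENOME,
) -> list[MatchHit]:
    """All ungapped full-length placements with Hamming distance <= max.

    Searches both strands; the reported strand is the genome strand the
    probe oligo anneals to as written. Complete by the pigeonhole argument
    provided the index seed length k <= probe_len // (max_mismatches + 1).
    Genome Ns count as mismatches. Hits are capped per genome at
    ``cap_per_genome`` (deterministically: lowest coordinates kept).
    """
    L = len(probe_seq)
    if max_mismatches >= L:
        raise ValueError("max_mismatches must be < probe length")
    if index.k > L // (max_mismatches + 1):
        raise ValueError(
            f"seed length {index.k} too long for {max_mismatches} mismatches "
            f"on a {L}-mer (pigeonhole requires k <= {L // (max_mismatches + 1)})"
        )
    fwd = sequtil.encode(sequtil.normalize(probe_seq))
    if (fwd >= 4).any():
        raise ValueError("probe must be fully specified (no N)")
    n_seeds = max_mismatches + 1
    hits: dict[tuple[int, int, str], int] = {}
    for strand, codes in (("+", fwd), ("-", sequtil.revcomp_codes(fwd))):
        for key, off in _probe_keys(codes, index.k, n_seeds):
            for ci, pos in index.seed_positions(key):
                start = int(pos) - off
                hkey = (int(ci), start, strand)
                if hkey in hits:
                    continue
                _, _, ref = index.contig(int(ci))
                if start < 0 or start + L > len(ref):
                    continue
                window = ref[start : start + L]
                # N in the genome never matches (N code 4 != any probe code)
                mm = int(np.count_nonzero(window != codes))
                if mm <= max_mismatches:
                    hits[hkey] = mm
    out = []
    per_genome: dict[str, int] = {}
    for (ci, start, strand), mm in sorted(hits.items()):
        gid, cid, _ = index.contig(ci)
        per_genome[gid] = per_genome.get(gid, 0) + 1
        if per_genome[gid] > cap_per_genome:
            continue
        out.append(MatchHit(genome_id=gid, contig_id=cid, pos=start, strand=strand, mismatches=mm))
    return out


def inclusion_screen(
    probe_seq: str, target_index: GenomeIndex, min_genomes: int
) -> dict:
    """Pass iff >=min_genomes target genomes hold a perfect match.

    Multiple perfect hits within one genome count once (per-genome tally).
    """
    hits = find_hits(probe_seq, target_index, max_mismatches=0)
    genomes = sorted({h.genome_id for h in hits})
    return {
        "pass": len(genomes) >= min_genomes,
        "n_genomes": len(genomes),
        "min_genomes": min_genomes,
    }


def exclusion_screen(
    probe_seq: str, offtarget_index: GenomeIndex | None, max_mismatches: int = 4
) -> dict:
    """Fail iff any off-target placement with <=max_mismatches exists.

    The offending hit (lowest mismatch count, then coordinates) is reported.
    An empty off-target set passes trivially.
    """
    if offtarget_index is None or not offtarget_index.genomes:
        return {"pass": True, "hit": None}
    hits = find_hits(probe_seq, offtarget_index, max_mismatches=max_mismatches)
    if not hits:
        return {"pass": True, "hit": None}
    best = min(hits, key=lambda h: (h.mismatches, h.genome_id, h.contig_id, h.pos))
    return {"pass": False, "hit": best}


class HostIndex:
    """Concatenated host-transcript array for exact diagonal scanning.

    Transcripts are joined with runs of N (which never match) long enough
    that no alignment diagonal crosses a transcript boundary; the leading
    and trailing pads also expose partial-overlap diagonals at the ends.
    """

    def __init__(self, transcripts: list[tuple[str, str]], probe_len: int = 40):
        self.probe_len = probe_len
        self.names = [name for name, _ in transcripts]
        pad = np.full(probe_len - 1, sequtil.N_CODE, dtype=np.uint8) if probe_len > 1 \
            else np.empty(0, dtype=np.uint8)
        pieces = [pad]
        self.starts = []  # start offset of each transcript in the joined array
        offset = len(pad)
        for _, s in transcripts:
            codes = sequtil.encode(sequtil.normalize(s))
            self.starts.append(offset)
            pieces.append(codes)
            offset += len(codes)
            pieces.append(pad)
            offset += len(pad)
        self.joined = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
        self.starts = np.asarray(self.starts, dtype=np.int64)

    def transcript_at(self, pos: int) -> str | None:
        if len(self.starts) == 0:
            return None
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        i = max(0, min(i, len(self.names) - 1))
        return self.names[i]


def _best_diagonal(probe: np.ndarray, joined: np.ndarray) -> tuple[int, int]:
    """(max matched bases, diagonal offset) over every ungapped diagonal."""
    L = len(probe)
    n_diag = len(joined) - L + 1
    if n_diag <= 0:
        return 0, 0
    counts = np.zeros(n_diag, dtype=np.int32)
    for i in range(L):
        counts += joined[i : i + n_diag] == probe[i]
    d = int(np.argmax(counts))
    return int(counts[d]), d


def host_screen(
    probe_seq: str,
    host: HostIndex | None,
    max_match_bases: int = 24,
    probe_id: str = "",
) -> dict:
    """Fail iff >max_match_bases bases of the probe match a host transcript.

    ``max_match_bases`` is the largest tolerated value (default 24, i.e.
    "<25 of 40 bases matching"). Matching is counted within the best
    ungapped alignment diagonal on either strand; internal mismatches are
    allowed and simply not counted. Exact, not seeded.
    """
    if host is None or len(getattr(host, "joined", ())) == 0:
        return {
            "pass": True,
            "result": HostMatchResult(probe_id=probe_id, max_match_bases=0),
        }
    fwd = sequtil.encode(sequtil.normalize(probe_seq))
    if (fwd >= 4).any():
        raise ValueError("probe must be fully specified (no N)")
    best, best_pos = -1, 0
    for codes in (fwd, sequtil.revcomp_codes(fwd)):
        m, d = _best_diagonal(codes, host.joined)
        if m > best:
            best, best_pos = m, d
    res = HostMatchResult(
        probe_id=probe_id,
        max_match_bases=max(best, 0),
        transcript_id=host.transcript_at(best_pos),
    )
    return {"pass": res.max_match_bases <= max_match_bases, "result": res}


def screen_probe(
    probe_seq: str,
    target_index: GenomeIndex,
    offtarget_index: GenomeIndex | None,
    host: HostIndex | None,
    min_genomes: int,
    exclusion_max_mismatches: int = 4,
    host_max_match_bases: int = 24,
    probe_id: str = "",
    short_circuit: bool = False,
) -> dict:
    """Run the three screens; returns {screen_name: verdict dict}.

    With ``short_circuit`` the screens run cheapest-first and stop at the
    first failure (the host scan is the expensive one); the returned dict
    then only contains the screens that ran.
    """
    out = {"inclusion": inclusion_screen(probe_seq, target_index, min_genomes)}
    if short_circuit and not out["inclusion"]["pass"]:
        return out
    out["exclusion"] = exclusion_screen(probe_seq, offtarget_index, exclusion_max_mismatches)
    if short_circuit and not out["exclusion"]["pass"]:
        return out
    out["host"] = host_screen(probe_seq, host, host_max_match_bases, probe_id=probe_id)
    return out
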