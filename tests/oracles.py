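"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: sliding windows, exhaustive subset
enumeration, closed-form textbook formulas. These functions never share
code paths with the package internals they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _enc(s: str) -> np.ndarray:
    return np.array([_CODE[b] for b in s], dtype=np.uint8)


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def hamming_scan(probe: str, genomes: list, max_mismatches: int) -> set:
    """All full-length ungapped placements with <=max_mismatches, both
    strands, by exhaustive sliding-window Hamming scan.

    ``genomes`` is a list of objects with .genome_id and .contigs.
    Returns {(genome_id, contig_id, pos, strand, mismatches)}. N in the
    genome always mismatches.
    """
    L = len(probe)
    out = set()
    for g in genomes:
        for cid, seq in g.contigs.items():
            if len(seq) < L:
                continue
            ref = _enc(seq)
            windows = sliding_window_view(ref, L)
            for strand, p in (("+", probe), ("-", _revcomp(probe))):
                pc = _enc(p)
                # N (code 4) never equals a probe code (0-3), so != suffices
                mism = (windows != pc).sum(axis=1)
                hits = np.flatnonzero(mism <= max_mismatches)
                for pos in hits:
                    out.add((g.genome_id, cid, int(pos), strand, int(mism[pos])))
    return out


def host_max_match(probe: str, transcripts: list) -> int:
    """Exhaustive max matched bases over every ungapped alignment diagonal
    of the probe (either strand) against every transcript, including
    partial overlaps at transcript ends."""
    L = len(probe)
    best = 0
    for _, seq in transcripts:
        padded = "N" * (L - 1) + seq.upper() + "N" * (L - 1)
        ref = _enc(padded)
        windows = sliding_window_view(ref, L)
        for p in (probe, _revcomp(probe)):
            pc = _enc(p)
            matches = (windows == pc).sum(axis=1)
            if len(matches):
                best = max(best, int(matches.max()))
    return best


def best_spacing_subset(starts: list[int], min_spacing: int) -> int:
    """Maximum-cardinality subset with pairwise distance >= min_spacing,
    by exhaustive subset enumeration (use only for <=20 points)."""
    n = len(starts)
    best = 0
    for mask in range(1 << n):
        sel = [starts[i] for i in range(n) if mask >> i & 1]
        sel.sort()
        if all(b - a >= min_spacing for a, b in zip(sel, sel[1:])):
            best = max(best, len(sel))
    return best


def max_mip_pairing(
    arm_starts: list[int], arm_len: int, gap_lo: int, gap_hi: int, min_spacing: int
) -> int:
    """Maximum number of valid MIP pairs by brute-force matching: each arm
    used at most once, gap within [gap_lo, gap_hi], left starts pairwise
    >= min_spacing apart. Exhaustive over all pair sets (<=10 arms)."""
    n = len(arm_starts)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j
        and gap_lo <= arm_starts[j] - (arm_starts[i] + arm_len) <= gap_hi
    ]
    best = 0
    for r in range(1, len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            arms = [a for p in combo for a in p]
            if len(set(arms)) != len(arms):
                continue
            lefts = sorted(arm_starts[i] for i, _ in combo)
            if all(b - a >= min_spacing for a, b in zip(lefts, lefts[1:])):
                best = max(best, r)
        if best < r:  # no feasible set of this size; larger ones impossible
            break
    return best


def nn_tm(seq: str, salt_mM: float = 50.0, oligo_nM: float = 0.25) -> float:
    """Published-parameter nearest-neighbor Tm via Biopython (independent
    implementation at identical salt/oligo settings)."""
    from Bio.SeqUtils import MeltingTemp as mt

    return float(
        mt.Tm_NN(
            seq,
            nn_table=mt.DNA_NN3,
            Na=salt_mM,
            dnac1=oligo_nM,
            dnac2=0,
            saltcorr=5,
        )
    )


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for a hypergeometric draw, by exact enumeration."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return acc / total


def wilcoxon_exact_two_sided(a: list[float], b: list[float]) -> float:
    """Exact two-sided rank-sum P by enumerating all group assignments.

    Requires all values distinct. P = fraction of assignments whose
    rank-sum statistic is at least as extreme as observed (two-sided by
    doubling the smaller tail, capped at 1)."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    w_obs = sum(ranks[v] for v in a)
    stats = [
        sum(combo)
        for combo in itertools.combinations(range(1, len(pooled) + 1), n_a)
    ]
    lo = sum(1 for w in stats if w <= w_obs) / len(stats)
    hi = sum(1 for w in stats if w >= w_obs) / len(stats)
    return min(1.0, 2 * min(lo, hi))


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted P values via the step-up closed form:
    adj_p(i) = min_{j>=i} ( m * p(j) / j ) on sorted p values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * pvals[i] / rank_from_top)
        adj[i] = running
    return adj


def poisson_wald_z(y_a: np.ndarray, y_b: np.ndarray) -> float:
    """Closed-form Wald z for log(mu_b/mu_a) under Poisson sampling:
    z = log(mean_b/mean_a) / sqrt(1/sum_a + 1/sum_b)."""
    sa, sb = float(np.sum(y_a)), float(np.sum(y_b))
    na, nb = len(y_a), len(y_b)
    beta = np.log((sb / nb) / (sa / na))
    se = np.sqrt(1.0 / sa + 1.0 / sb)
    return float(beta / se)
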