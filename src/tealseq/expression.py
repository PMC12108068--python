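"""Probe-level differential expression and gene-level aggregation.

Per probe, a negative-binomial GLM (log link, library-size offsets) is fit
over a two-factor design (condition plus an optional covariate, with
interaction) and the condition coefficient is tested by Wald. Dispersion is
a method-of-moments estimate with a small-sample floor; with few replicates
the pooled (common) estimate across probes is the default, per-probe
estimation is available. This engine deliberately does not reproduce
DESeq2's size-factor/shrinkage machinery; it recovers planted effects, not
DESeq2 coefficients.

Genes are called from the medians of their probes: a gene is differentially
expressed when |median probe log2FC| exceeds the fold-change threshold
(default 2, i.e. four-fold) and the median BH-adjusted P value is below the
significance threshold (default 0.05). The median-of-probes rule is robust
to individual poorly performing probes.

Also provided: directional gene-set over-representation (upper-tail
hypergeometric with Bonferroni adjustment over the batch of comparisons),
sum-of-squared-error comparison of paired log2 expression profiles with an
exact Wilcoxon rank-sum test, and pairwise Pearson correlation / distance
matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5  # for reported log2 fold changes only
DISPERSION_FLOOR = 1e-8


@dataclass
class DeDesign:
    """Sample design: condition (tested, two levels) plus optional covariate."""

    condition: pd.Series  # sample -> level (reference = first sorted level)
    covariate: pd.Series | None = None
    interaction: bool = True

    def matrix(self, samples: list[str]) -> tuple[np.ndarray, list[str]]:
        cond = self.condition.loc[samples].astype(str)
        levels = sorted(cond.unique())
        if len(levels) != 2:
            raise ValueError(f"condition must have exactly 2 levels, got {levels}")
        x_cond = (cond == levels[1]).to_numpy(float)
        cols = [np.ones(len(samples)), x_cond]
        names = ["intercept", f"condition[{levels[1]}]"]
        if self.covariate is not None:
            cov = self.covariate.loc[samples].astype(str)
            clevels = sorted(cov.unique())
            for lv in clevels[1:]:
                x = (cov == lv).to_numpy(float)
                cols.append(x)
                names.append(f"covariate[{lv}]")
                if self.interaction:
                    cols.append(x * x_cond)
                    names.append(f"condition[{levels[1]}]:covariate[{lv}]")
        return np.column_stack(cols), names


def size_factors(counts: pd.DataFrame, method: str = "library") -> pd.Series:
    """Per-sample scaling factors (geometric-mean normalized).

    ``library``: total-count scaling. ``median_of_ratios``: DESeq-style
    median ratio to the geometric reference gene-wise profile.
    """
    if method == "library":
        lib = counts.sum(axis=0).astype(float)
        if (lib <= 0).any():
            raise ValueError("sample with zero total counts")
        return lib / np.exp(np.log(lib).mean())
    if method == "median_of_ratios":
        logc = np.log(counts.replace(0, np.nan))
        ref = logc.mean(axis=1)
        ratios = logc.sub(ref, axis=0)
        sf = np.exp(ratios.median(axis=0, skipna=True))
        return sf / np.exp(np.log(sf).mean())
    raise ValueError(f"unknown size-factor method {method!r}")


def _mom_alpha(y: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion from within-group mean/variance."""
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = y[groups == g]
        if len(sub) < 2:
            continue
        m = sub.mean()
        v = sub.var(ddof=1)
        num += v - m
        den += m * m
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def probe_de(
    counts: pd.DataFrame,  # probes x samples, raw integer counts
    design: DeDesign,
    gene_of_probe: pd.Series | None = None,
    dispersion: str = "common",
    sf_method: str = "library",
) -> pd.DataFrame:
    """Per-probe NB Wald test on the condition coefficient.

    Returns a frame with probe_id, gene_id, base_mean, log2fc, p, adj_p.
    All-zero probes are excluded (reported via the ``excluded`` attribute
    on the returned frame). BH adjustment runs across all tested probes.
    """
    samples = list(counts.columns)
    X, names = design.matrix(samples)
    cond_idx = names.index([n for n in names if n.startswith("condition[")][0])
    sf = size_factors(counts, sf_method).loc[samples]
    offset = np.log(sf.to_numpy())

    nonzero = counts.sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    sub = counts.loc[nonzero]
    norm = sub.div(sf, axis=1)

    # group labels = distinct design rows, for MoM dispersion
    groups = np.unique(X, axis=0, return_inverse=True)[1]
    alphas = np.array([_mom_alpha(norm.loc[p].to_numpy(), groups) for p in sub.index])
    means = norm.mean(axis=1).to_numpy()
    informative = means >= 5
    common = float(np.median(alphas[informative])) if informative.any() else 0.0
    common = max(common, DISPERSION_FLOOR)

    cond = design.condition.loc[samples].astype(str)
    lvl = sorted(cond.unique())
    a_cols = cond == lvl[0]
    b_cols = cond == lvl[1]

    rows = []
    for i, pid in enumerate(sub.index):
        y = sub.loc[pid].to_numpy(float)
        alpha = common if dispersion == "common" else max(alphas[i], DISPERSION_FLOOR)
        p_val = _nb_wald_p(y, X, cond_idx, alpha, offset)
        nv = norm.loc[pid]
        log2fc = float(
            np.log2(nv[b_cols].mean() + PSEUDOCOUNT) - np.log2(nv[a_cols].mean() + PSEUDOCOUNT)
        )
        rows.append(
            {
                "probe_id": pid,
                "gene_id": gene_of_probe.get(pid, pid) if gene_of_probe is not None else pid,
                "base_mean": float(nv.mean()),
                "log2fc": log2fc,
                "p": p_val,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["adj_p"] = []
    out.attrs["excluded"] = excluded
    out.attrs["common_dispersion"] = common
    return out


def _nb_wald_p(
    y: np.ndarray, X: np.ndarray, coef_idx: int, alpha: float, offset: np.ndarray
) -> float:
    """Two-sided Wald P for one coefficient of an NB GLM; NaN-safe."""
    fam = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            beta = fit.params[coef_idx]
            se = fit.bse[coef_idx]
        except Exception:
            return 1.0
    if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return 1.0
    z = beta / se
    return float(2 * stats.norm.sf(abs(z)))


def aggregate_genes(
    probe_results: pd.DataFrame, lfc_thresh: float = 2.0, p_thresh: float = 0.05
) -> pd.DataFrame:
    """Median-of-probes gene calls.

    Medians are interpolated for even probe counts. Call is ``up`` when
    median_log2fc > lfc_thresh (strict) and median_adj_p < p_thresh,
    ``down`` symmetric, else ``ns``.
    """
    rows = []
    for gid, sub in probe_results.groupby("gene_id"):
        med_fc = float(np.median(sub["log2fc"]))
        med_p = float(np.median(sub["adj_p"]))
        if med_fc > lfc_thresh and med_p < p_thresh:
            call = "up"
        elif med_fc < -lfc_thresh and med_p < p_thresh:
            call = "down"
        else:
            call = "ns"
        rows.append(
            {
                "gene_id": gid,
                "n_probes": len(sub),
                "median_log2fc": med_fc,
                "median_adj_p": med_p,
                "call": call,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


@dataclass
class OverlapTest:
    """Hypergeometric over-representation of a query set in a reference set."""

    label: str
    universe_size: int
    reference_size: int
    query_size: int
    overlap: int
    p_hyper: float
    p_bonferroni: float


def overrep_test(
    query: set, reference: set, universe: set, n_comparisons: int = 1, label: str = ""
) -> OverlapTest:
    """Upper-tail hypergeometric P(X >= k) with Bonferroni adjustment.

    The Bonferroni multiplier is the number of set comparisons performed in
    the batch (caller-supplied; recorded in the result).
    """
    if not universe:
        raise ValueError("empty universe")
    if not (query <= universe and reference <= universe):
        raise ValueError("query and reference must be subsets of the universe")
    N, K, n = len(universe), len(reference), len(query)
    k = len(query & reference)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(
        label=label,
        universe_size=N,
        reference_size=K,
        query_size=n,
        overlap=k,
        p_hyper=min(p, 1.0),
        p_bonferroni=min(p * n_comparisons, 1.0),
    )


@dataclass
class SseResult:
    label_a: str
    label_b: str
    errors_a: np.ndarray  # per-CDS squared errors
    errors_b: np.ndarray
    sse_a: float
    sse_b: float
    wilcoxon_p: float


def paired_squared_errors(
    log2cpm: pd.DataFrame, pairs: list[tuple[str, str]]
) -> np.ndarray:
    """Per-CDS squared log2 differences, averaged over the sample pairs."""
    errs = np.zeros(len(log2cpm))
    for a, b in pairs:
        d = log2cpm[a].to_numpy() - log2cpm[b].to_numpy()
        errs += d * d
    return errs / max(len(pairs), 1)


def sse_compare(
    cpm: pd.DataFrame,  # CDS x samples CPM table
    pairing_a: list[tuple[str, str]],
    pairing_b: list[tuple[str, str]],
    label_a: str = "A",
    label_b: str = "B",
) -> SseResult:
    """Compare protocol-induced distortion between two pairings.

    Squared errors are computed per CDS on log2(CPM + 1); the two error
    distributions are compared by a two-sided Wilcoxon rank-sum test (exact
    for <=25 per group without ties, normal approximation with tie
    correction otherwise).
    """
    log2cpm = np.log2(cpm + 1.0)
    errs_a = paired_squared_errors(log2cpm, pairing_a)
    errs_b = paired_squared_errors(log2cpm, pairing_b)
    return SseResult(
        label_a=label_a,
        label_b=label_b,
        errors_a=errs_a,
        errors_b=errs_b,
        sse_a=float(errs_a.sum()),
        sse_b=float(errs_b.sum()),
        wilcoxon_p=rank_sum_p(errs_a, errs_b),
    )


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    exact = len(a) <= 25 and len(b) <= 25 and len(np.unique(np.r_[a, b])) == len(a) + len(b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def correlations(
    cpm: pd.DataFrame, log_transform: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise sample Pearson R matrix (+ P values) and the Euclidean
    distance matrix between correlation-matrix rows.

    Zero-variance samples get NaN rows/columns (reported missing, not 0).
    """
    x = np.log2(cpm + 1.0) if log_transform else cpm.copy()
    samples = list(x.columns)
    n = len(samples)
    R = np.full((n, n), np.nan)
    P = np.full((n, n), np.nan)
    var_ok = x.std(axis=0).to_numpy() > 0
    for i in range(n):
        for j in range(i, n):
            if not (var_ok[i] and var_ok[j]):
                continue
            if i == j:
                R[i, j], P[i, j] = 1.0, 0.0
                continue
            r, p = stats.pearsonr(x.iloc[:, i], x.iloc[:, j])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    Rdf = pd.DataFrame(R, index=samples, columns=samples)
    Pdf = pd.DataFrame(P, index=samples, columns=samples)
    D = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if var_ok[i] and var_ok[j]:
                D[i, j] = float(np.sqrt(np.nansum((R[i] - R[j]) ** 2)))
    Ddf = pd.DataFrame(D, index=samples, columns=samples)
    return Rdf, Pdf, Ddf
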