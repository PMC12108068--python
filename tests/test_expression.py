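"""Differential expression engine, gene aggregation and the statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import oracles
from tealseq import expression as te


def _design(samples, conditions):
    return te.DeDesign(condition=pd.Series(conditions, index=samples))


class TestProbeDe:
    def _null_counts(self, rng, n_probes=60, n=6, mu=100.0):
        counts = rng.poisson(mu, size=(n_probes, n))
        return pd.DataFrame(counts, index=[f"p{i}" for i in range(n_probes)],
                            columns=[f"s{i}" for i in range(n)])

    def test_null_data_gives_flat_fold_changes_and_calibrated_p(self, rng):
        counts = self._null_counts(rng)
        design = _design(list(counts.columns), ["A", "A", "A", "B", "B", "B"])
        res = te.probe_de(counts, design)
        assert abs(np.median(res["log2fc"])) < 0.2
        assert (res["p"] < 0.05).mean() < 0.2  # no systematic inflation
        assert (res["adj_p"] >= res["p"] - 1e-12).all()

    def test_recovers_planted_fold_change(self, rng):
        """Probes planted at true log2FC = 3 (a minority, so normalization
        is anchored by null probes) are estimated within +/-0.5."""
        n, n_de = 40, 10
        base = rng.lognormal(5, 0.3, size=n)
        mult = np.ones(n)
        mult[:n_de] = 8.0
        a = rng.poisson(np.tile(base[:, None], 3))
        b = rng.poisson(np.tile((base * mult)[:, None], 3))
        counts = pd.DataFrame(
            np.hstack([a, b]), index=[f"p{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(6)],
        )
        design = _design(list(counts.columns), ["A"] * 3 + ["B"] * 3)
        res = te.probe_de(counts, design, sf_method="median_of_ratios").set_index("probe_id")
        planted = [f"p{i}" for i in range(n_de)]
        null = [f"p{i}" for i in range(n_de, n)]
        assert np.mean(res.loc[planted, "log2fc"]) == pytest.approx(3.0, abs=0.5)
        assert np.abs(np.mean(res.loc[null, "log2fc"])) < 0.3
        assert (res.loc[planted, "adj_p"] < 0.05).mean() > 0.9

    def test_poisson_limit_matches_closed_form_wald(self, rng):
        """With dispersion -> 0 the NB Wald statistic approaches the
        closed-form Poisson Wald on the same counts (within 10%)."""
        n_probes, mu = 300, 80.0
        counts = pd.DataFrame(
            rng.poisson(mu, size=(n_probes, 10)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=[f"s{i}" for i in range(10)],
        )
        # equalize library sizes so offsets are zero and the closed form applies
        design = _design(list(counts.columns), ["A"] * 5 + ["B"] * 5)
        res = te.probe_de(counts, design)
        assert res.attrs["common_dispersion"] < 0.01
        zs = stats.norm.isf(res["p"] / 2)
        ref = np.array(
            [
                abs(
                    oracles.poisson_wald_z(
                        counts.loc[p][:5].to_numpy() / sf_a,
                        counts.loc[p][5:].to_numpy() / sf_b,
                    )
                )
                for p, sf_a, sf_b in zip(res["probe_id"], [1.0] * n_probes, [1.0] * n_probes)
            ]
        )
        big = ref > 1.0  # avoid ratio blow-up at z ~ 0
        assert np.median(np.abs(zs[big] - ref[big]) / ref[big]) < 0.10

    def test_all_zero_probes_excluded_and_reported(self, rng):
        counts = self._null_counts(rng, n_probes=5)
        counts.iloc[2] = 0
        design = _design(list(counts.columns), ["A"] * 3 + ["B"] * 3)
        res = te.probe_de(counts, design)
        assert "p2" not in set(res["probe_id"])
        assert res.attrs["excluded"] == ["p2"]

    def test_covariate_with_interaction_accepted(self, rng):
        counts = self._null_counts(rng, n_probes=20, n=8)
        samples = list(counts.columns)
        design = te.DeDesign(
            condition=pd.Series(["A"] * 4 + ["B"] * 4, index=samples),
            covariate=pd.Series(["x", "y"] * 4, index=samples),
            interaction=True,
        )
        res = te.probe_de(counts, design)
        assert len(res) == 20 and res["p"].between(0, 1).all()


class TestAggregateGenes:
    def _frame(self, fcs, ps, gene="g1"):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(fcs))],
                "gene_id": [gene] * len(fcs),
                "log2fc": fcs,
                "p": ps,
                "adj_p": ps,
            }
        )

    def test_median_and_up_call(self):
        res = te.aggregate_genes(self._frame([1.0, 2.5, 4.0], [0.01, 0.01, 0.2]))
        row = res.iloc[0]
        assert row["median_log2fc"] == 2.5
        assert row["median_adj_p"] == 0.01
        assert row["call"] == "up"

    def test_outlier_probe_does_not_flip_call(self):
        res = te.aggregate_genes(self._frame([2.4, 2.6, -8.0], [0.01] * 3))
        assert res.iloc[0]["median_log2fc"] == pytest.approx(2.4)
        assert res.iloc[0]["call"] == "up"

    def test_threshold_is_strict_inequality(self):
        res = te.aggregate_genes(self._frame([1.9, 2.1], [0.01] * 2))
        assert res.iloc[0]["median_log2fc"] == pytest.approx(2.0)  # interpolated
        assert res.iloc[0]["call"] == "ns"

    def test_down_call_symmetric(self):
        res = te.aggregate_genes(self._frame([-3.0, -2.5], [0.001] * 2))
        assert res.iloc[0]["call"] == "down"

    def test_calls_invariant_to_probe_order(self, rng):
        fcs = list(rng.normal(0, 3, size=9))
        ps = list(rng.uniform(0, 1, size=9))
        genes = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        df = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(9)], "gene_id": genes,
             "log2fc": fcs, "p": ps, "adj_p": ps}
        )
        shuffled = df.sample(frac=1, random_state=1)
        a = te.aggregate_genes(df)
        b = te.aggregate_genes(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestOverrepTest:
    def test_known_exact_case(self):
        universe = set(range(10))
        ref = set(range(5))
        query = {0, 1, 2, 3}
        t = te.overrep_test(query, ref, universe)
        assert t.overlap == 4
        assert t.p_hyper == pytest.approx(5 / 210)

    def test_zero_overlap_p_is_one(self):
        t = te.overrep_test({5, 6}, {0, 1}, set(range(10)))
        assert t.p_hyper == pytest.approx(1.0)

    def test_degenerate_full_overlap_certain(self):
        u = set(range(6))
        t = te.overrep_test(u, u, u)
        assert t.p_hyper == pytest.approx(1.0)

    def test_bonferroni_multiplier(self):
        u = set(range(10))
        t = te.overrep_test(set(range(4)), set(range(5)), u, n_comparisons=4)
        assert t.p_bonferroni == pytest.approx(min(1.0, 4 * t.p_hyper))

    def test_matches_enumeration_for_all_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expect = oracles.hypergeom_upper_tail(N, K, n, k)
                        got = float(stats.hypergeom.sf(k - 1, N, K, n))
                        assert got == pytest.approx(expect, rel=1e-9), (N, K, n, k)
        # and through the public API for a sample of cases
        u = set(range(12))
        t = te.overrep_test(set(range(6)), set(range(3, 11)), u)
        assert t.p_hyper == pytest.approx(
            oracles.hypergeom_upper_tail(12, 8, 6, t.overlap)
        )


class TestSse:
    def _cpm(self):
        return pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 5.0]},
            index=["g1", "g2", "g3"],
        )

    def test_squared_error_arithmetic(self):
        log2cpm = self._cpm()  # use values directly as log2 profiles
        errs = te.paired_squared_errors(log2cpm, [("s1", "s2")])
        assert errs.tolist() == [0.0, 0.0, 4.0]

    def test_identical_profiles_zero_sse(self):
        r = te.sse_compare(self._cpm(), [("s1", "s1")], [("s2", "s2")])
        assert r.sse_a == 0.0 and r.sse_b == 0.0

    def test_exact_wilcoxon_small_case(self):
        assert te.rank_sum_p(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == pytest.approx(1 / 3)

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=8, unique=True),
        st.lists(st.integers(10_001, 20_000), min_size=2, max_size=8, unique=True),
    )
    def test_exact_wilcoxon_matches_enumeration(self, a, b):
        a = [float(x) for x in a]
        b = [float(x) for x in b]
        assert te.rank_sum_p(np.array(a), np.array(b)) == pytest.approx(
            oracles.wilcoxon_exact_two_sided(a, b)
        )


class TestBh:
    def test_matches_stepup_closed_form(self):
        pvals = [0.01, 0.02, 0.03, 0.5, 0.04, 1.0, 0.005]
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(adj, oracles.bh_stepup(pvals))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_in_p(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert np.allclose(adj, oracles.bh_stepup(pvals))


class TestCorrelations:
    def test_perfect_and_anti_correlation(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 3, 2, 1]})
        R, P, D = te.correlations(df, log_transform=False)
        assert R.loc["a", "b"] == pytest.approx(1.0)
        assert R.loc["a", "c"] == pytest.approx(-1.0)
        assert D.loc["a", "b"] == pytest.approx(0.0)

    def test_hand_computed_four_vector(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 3.0, 3.0, 8.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        df = pd.DataFrame({"a": x, "b": y})
        R, _, _ = te.correlations(df, log_transform=False)
        assert R.loc["a", "b"] == pytest.approx(r_hand)

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        R, P, D = te.correlations(df, log_transform=False)
        assert np.isnan(R.loc["a", "b"]) and np.isnan(D.loc["a", "b"])
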