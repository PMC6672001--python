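"""Unit and property tests for the shared statistics layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from callosal import stats
from callosal.errors import ValidationError


def holm_sidak_oracle(p, alpha=0.05):
    """Literal step-down: walk the sorted p-values, adjust each with the
    number of remaining hypotheses, enforce monotonicity by brute force."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank, idx in enumerate(order):
        candidates = [1 - (1 - p[order[j]]) ** (m - j) for j in range(rank + 1)]
        adj[idx] = min(1.0, max(candidates))
    return adj, adj < alpha


class TestTwoSampleT:
    def test_identical_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        res = stats.two_sample_t(a, a.copy())
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_df_is_pooled_sample_sizes_minus_two(self, rng):
        res = stats.two_sample_t(rng.normal(size=7), rng.normal(size=6))
        assert res.df == 11

    def test_matches_independent_R_computation(self):
        # frozen oracle: t.test(a, b, var.equal=TRUE) in R 4.3.3
        a = [4.6, 5.1, 5.8, 6.5, 4.9]
        b = [3.9, 4.4, 4.1, 5.0, 4.2, 4.6]
        res = stats.two_sample_t(a, b)
        assert res.statistic == pytest.approx(2.841632, abs=1e-6)
        assert res.p == pytest.approx(0.01935157, abs=1e-7)

    def test_zero_variance_unequal_means(self):
        res = stats.two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and "zero_variance" in res.flags

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValidationError):
            stats.two_sample_t([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_complete_separation_and_symmetry(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        # exact two-tailed p: 2/20 orderings are as extreme
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_half_product(self):
        res = stats.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # nA*nB/2


class TestKolmogorovSmirnov:
    def test_identical_and_disjoint(self, rng):
        x = rng.normal(size=30)
        assert stats.ks_two_sample(x, x).statistic == 0.0
        assert stats.ks_two_sample(x, x + 100.0).statistic == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        a, b = rng.normal(size=25), rng.normal(0.5, 1, size=20)
        d1 = stats.ks_two_sample(a, b).statistic
        d2 = stats.ks_two_sample(np.exp(a), np.exp(b)).statistic
        assert d1 == pytest.approx(d2)


class TestHolmSidak:
    def test_single_p_unchanged(self):
        adj, rej = stats.holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_two_p_worked_example(self):
        # smallest gets 1-(1-0.01)^2 = 0.0199; the larger keeps max(0.04, 0.0199)
        adj, _ = stats.holm_sidak([0.01, 0.04])
        assert adj == pytest.approx([0.0199, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            stats.holm_sidak([0.5, 1.2])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_bruteforce_oracle(self, pvals):
        adj, rej = stats.holm_sidak(pvals)
        oadj, orej = holm_sidak_oracle(pvals)
        assert np.allclose(adj, oadj)
        assert np.array_equal(rej, orej)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(size=8)
        adj, _ = stats.holm_sidak(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSidak:
    def test_single_step_formula(self):
        assert stats.sidak_adjust(0.01, 5) == pytest.approx(1 - 0.99 ** 5)
        assert stats.sidak_adjust(0.2, 1) == 0.2

    @given(st.floats(0, 1), st.integers(1, 20))
    def test_adjusted_never_below_raw(self, p, m):
        assert stats.sidak_adjust(p, m) >= p - 1e-15


class TestTwoWayAnova:
    def test_df_for_2x2_design(self, rng):
        n = 40
        fa = rng.integers(0, 2, n)
        fb = rng.integers(0, 2, n)
        res = stats.two_way_anova(rng.normal(size=n), fa, fb)
        assert res["AxB"].df == (1, n - 4)

    def test_null_f_near_one_on_average(self, rng):
        fs = []
        for _ in range(200):
            y = rng.normal(size=24)
            fa = np.repeat([0, 1], 12)
            fb = np.tile(np.repeat([0, 1, 2], 4), 2)
            fs.append(stats.two_way_anova(y, fa, fb)["A"].statistic)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_single_level_factor_rejected(self, rng):
        with pytest.raises(ValidationError):
            stats.two_way_anova(rng.normal(size=10), np.zeros(10),
                                rng.integers(0, 2, 10))


class TestMixedAnova:
    @pytest.mark.parametrize("n_a,n_b,df2", [(15, 16, 29), (14, 15, 27),
                                             (11, 8, 17), (8, 12, 18)])
    def test_between_subject_df(self, rng, n_a, n_b, df2):
        """Between-group df is (1, N_subjects - 2) for two groups."""
        rows = []
        for g, n in (("a", n_a), ("b", n_b)):
            for s in range(n):
                for w in range(4):
                    rows.append((rng.normal(), g, w, f"{g}{s}"))
        y, g, w, s = map(np.array, zip(*rows))
        fit = stats.two_way_rm_anova(y, g, w, s)
        assert fit.results["between"].df == (1, df2)

    def test_matches_pingouin_unbalanced(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rows = []
        for g, n in (("wt", 7), ("het", 9)):
            for s in range(n):
                base = rng.normal(0 if g == "wt" else 1.0)
                for w in range(3):
                    rows.append((base + 0.5 * w + rng.normal(), g, w, f"{g}{s}"))
        df = pd.DataFrame(rows, columns=["y", "g", "w", "s"])
        fit = stats.two_way_rm_anova(df.y, df.g, df.w, df.s)
        pg = pingouin.mixed_anova(data=df, dv="y", between="g", within="w",
                                  subject="s")
        pg = pg.set_index("Source")
        assert fit.results["between"].statistic == pytest.approx(
            pg.loc["g", "F"], rel=1e-9)
        assert fit.results["within"].statistic == pytest.approx(
            pg.loc["w", "F"], rel=1e-9)
        assert fit.results["interaction"].statistic == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-9)

    def test_zero_within_variance_equal_means(self):
        y, g, w, s = [], [], [], []
        for gi, grp in enumerate(("a", "b")):
            for si in range(3):
                for wi in range(2):
                    y.append(1.0)
                    g.append(grp)
                    w.append(wi)
                    s.append(f"{grp}{si}")
        fit = stats.two_way_rm_anova(y, g, w, s)
        assert fit.results["between"].statistic == 0.0

    def test_incomplete_subject_excluded(self, rng):
        rows = [(rng.normal(), "a", w, "a0") for w in range(3)]
        rows += [(rng.normal(), "a", w, "a1") for w in range(3)]
        rows += [(rng.normal(), "b", w, "b0") for w in range(3)]
        rows += [(rng.normal(), "b", w, "b1") for w in range(3)]
        rows += [(rng.normal(), "b", 0, "b2")]  # misses within levels 1, 2
        y, g, w, s = map(np.array, zip(*rows))
        fit = stats.two_way_rm_anova(y, g, w, s)
        assert fit.results["between"].df == (1, 2)
        assert any("excluded" in f for f in fit.results["between"].flags)


class TestSidakPosthoc:
    def test_adjustment_and_unknown_cell(self, rng):
        rows = []
        for g, n in (("a", 6), ("b", 6)):
            for s in range(n):
                for w in range(4):
                    rows.append((rng.normal(2.0 if (g == "b" and w == 0) else 0.0),
                                 g, w, f"{g}{s}"))
        y, g, w, s = map(np.array, zip(*rows))
        fit = stats.two_way_rm_anova(y, g, w, s)
        post = stats.sidak_posthoc(fit)
        assert len(post) == 4
        for res in post.values():
            assert res.p_adjusted >= res.p - 1e-15
        with pytest.raises(ValidationError):
            stats.sidak_posthoc(fit, comparisons=[("a", "b", "nope")])
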