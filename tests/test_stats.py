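"""Statistical layer: exact-test oracles, survival, bootstrap, rm-ANOVA."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from zfseizure import stats


# ---------------------------------------------------------------------------
# independent Barnard oracle: direct definition, dense grid + refinement
# ---------------------------------------------------------------------------


def barnard_oracle(k1, n1, k2, n2, alternative, statistic="score", grid=4001):
    T = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            p1, p2 = i / n1, j / n2
            if p1 == p2:
                continue
            if statistic == "score":
                pp = (i + j) / (n1 + n2)
                var = pp * (1 - pp) * (1 / n1 + 1 / n2)
            else:
                var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
            T[i, j] = (p1 - p2) / np.sqrt(var) if var > 0 else np.inf * np.sign(p1 - p2)
    t_obs = T[k1, k2]
    if alternative == "one_sided":
        cells = [(i, j) for i in range(n1 + 1) for j in range(n2 + 1)
                 if (T[i, j] >= t_obs - 1e-12 if t_obs >= 0 else T[i, j] <= t_obs + 1e-12)]
    else:
        cells = [(i, j) for i in range(n1 + 1) for j in range(n2 + 1)
                 if abs(T[i, j]) >= abs(t_obs) - 1e-12]
    c1 = np.array([comb(n1, i) for i, _ in cells], dtype=float)
    c2 = np.array([comb(n2, j) for _, j in cells], dtype=float)
    i_arr = np.array([i for i, _ in cells])
    j_arr = np.array([j for _, j in cells])

    def p_of(pi):
        pi = np.atleast_1d(pi)
        terms = (c1 * c2) * pi[:, None] ** (i_arr + j_arr) \
            * (1 - pi[:, None]) ** (n1 - i_arr + n2 - j_arr)
        return terms.sum(axis=1)

    pis = np.linspace(0.0, 1.0, grid)
    vals = p_of(pis)
    best = vals.max()
    i = int(vals.argmax())
    lo, hi = pis[max(i - 1, 0)], pis[min(i + 1, grid - 1)]
    res = minimize_scalar(lambda p: -p_of(np.array([p]))[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(min(max(best, -res.fun), 1.0))


class TestBarnard:
    @pytest.mark.parametrize("table,expected", [
        ((7, 7, 0, 7), 0.5 ** 14),   # fully separated: closed form
        ((7, 7, 9, 9), 1.0),          # both groups at 100%
        ((2, 4, 2, 4), 1.0),          # identical proportions
    ])
    def test_analytic_values(self, table, expected):
        p = stats.barnard_exact(*table, alternative="one_sided")
        assert p == pytest.approx(expected, rel=1e-9)

    def test_incidence_table_7of7_vs_4of12(self):
        p = stats.barnard_exact(7, 7, 4, 12, alternative="one_sided")
        assert p == pytest.approx(4.5e-3, abs=0.05e-3)

    def test_incidence_table_7of7_vs_1of8(self):
        # one-sided unconditional p for the knockout incidence table; the
        # same value arises from score, Wald and Boschloo orderings
        p = stats.barnard_exact(7, 7, 1, 8, alternative="one_sided")
        assert p == pytest.approx(2.804e-4, rel=1e-3)

    def test_one_sided_never_exceeds_two_sided(self):
        for (k1, n1, k2, n2) in [(5, 6, 1, 6), (3, 5, 3, 7), (0, 4, 4, 4)]:
            p1 = stats.barnard_exact(k1, n1, k2, n2, alternative="one_sided")
            p2 = stats.barnard_exact(k1, n1, k2, n2, alternative="two_sided")
            assert p1 <= p2 + 1e-12

    @pytest.mark.parametrize("alternative", ["one_sided", "two_sided"])
    def test_matches_enumeration_oracle_small_designs(self, alternative):
        for n1, n2 in [(3, 3), (3, 5), (5, 5)]:
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    p = stats.barnard_exact(k1, n1, k2, n2, alternative=alternative)
                    p_ref = barnard_oracle(k1, n1, k2, n2, alternative)
                    assert p == pytest.approx(p_ref, abs=1e-6)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            stats.barnard_exact(0, 0, 1, 5)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.data())
    def test_pvalue_in_unit_interval(self, data):
        n1 = data.draw(st.integers(1, 8))
        n2 = data.draw(st.integers(1, 8))
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        p = stats.barnard_exact(k1, n1, k2, n2, alternative="two_sided")
        assert 0.0 <= p <= 1.0


class TestFisher:
    def test_balanced_table_p_one(self):
        _, p = stats.fisher_exact_2x2(3, 6, 3, 6)
        assert p == 1.0

    def test_fully_separated_two_sided_closed_form(self):
        _, p = stats.fisher_exact_2x2(7, 7, 0, 7)
        assert p == pytest.approx(2 / comb(14, 7), rel=1e-9)

    def test_matches_hypergeometric_enumeration(self):
        # one-sided tail sums via math.comb, independent of scipy
        for n1, n2 in [(4, 4), (5, 7), (6, 6)]:
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    m = k1 + k2
                    denom = comb(n1 + n2, m)
                    tail = sum(
                        comb(n1, i) * comb(n2, m - i)
                        for i in range(k1, min(n1, m) + 1)
                        if 0 <= m - i <= n2
                    ) / denom
                    _, p = stats.fisher_exact_2x2(k1, n1, k2, n2, "one_sided")
                    assert p == pytest.approx(tail, rel=1e-9)


class TestRankTests:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = stats.mann_whitney_u(x, x)
        assert p == pytest.approx(1.0)

    def test_fully_separated_exact_p(self):
        # all y above all x: one-sided p = 1 / C(6, 3)
        _, p = stats.mann_whitney_u([4, 5, 6], [1, 2, 3], alternative="one_sided")
        assert p == pytest.approx(1 / comb(6, 3), rel=1e-9)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(4, 4), (5, 6), (6, 6)]:
            x = rng.normal(0.5, 1, n1)
            y = rng.normal(0, 1, n2)
            _, p = stats.mann_whitney_u(x, y, alternative="one_sided")
            pooled = np.concatenate([x, y])
            n = len(pooled)
            u_obs = sum(1 for a in x for b in y if a > b)
            count = 0
            total = 0
            for idx in combinations(range(n), n1):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                u = sum(1 for a in xs for b in ys if a > b)
                total += 1
                count += u >= u_obs
            assert p == pytest.approx(count / total, abs=1e-9)

    def test_normal_approximation_close_to_exact_n8(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.8, 1, 8)
        y = rng.normal(0.0, 1, 8)
        from scipy.stats import mannwhitneyu

        p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        p_approx = mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").pvalue
        assert p_approx == pytest.approx(p_exact, abs=0.01)

    def test_wilcoxon_and_kruskal_basic(self):
        x = np.array([1.2, 0.8, 1.5, 2.0, 0.3, 1.1])
        _, p = stats.wilcoxon_signed_rank(x, x + 2.0)
        assert p < 0.05
        h, p_kw = stats.kruskal_wallis([1, 2, 3], [1.1, 2.1, 3.1], [0.9, 1.9, 2.9])
        assert p_kw > 0.5


class TestSurvival:
    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5.0, 40)
        data = pd.DataFrame({"time": times, "event": 1})
        km = stats.kaplan_meier(data)
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-9)

    def test_two_deaths_step_function(self):
        data = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]})
        km = stats.kaplan_meier(data)
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(0.5)
        assert lookup[2.0] == pytest.approx(0.0)

    def test_no_deaths_survival_one(self):
        data = pd.DataFrame({"time": [5.0] * 10, "event": [0] * 10})
        km = stats.kaplan_meier(data)
        assert (km["survival"] == 1.0).all()

    def test_identical_groups_logrank_zero(self):
        data = pd.DataFrame({"time": [1, 2, 3, 4, 5.0], "event": [1, 0, 1, 1, 0]})
        chi2, p = stats.logrank(data, data)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)


class TestBootstrap:
    def test_constant_equal_samples_zero_ci(self):
        x = np.full(10, 3.0)
        res = stats.bootstrap_diff_means(x, x, n_boot=500, seed=0)
        assert res.difference == 0.0
        assert res.ci_low == res.ci_high == 0.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        r1 = stats.bootstrap_diff_means(x, y, seed=42)
        r2 = stats.bootstrap_diff_means(x, y, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_coverage_of_true_shift(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(0, 1, 25)
            y = rng.normal(1, 1, 25)
            res = stats.bootstrap_diff_means(x, y, n_boot=1000,
                                             seed=int(rng.integers(2**31)))
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert 0.90 <= hits / n_sim <= 0.99


class TestRMAnova:
    def test_two_levels_epsilon_exactly_one(self):
        rng = np.random.default_rng(5)
        assert stats.gg_epsilon(rng.normal(size=(30, 2))) == pytest.approx(1.0)

    def test_epsilon_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        rows = []
        for s in range(15):
            base = rng.normal()
            for t in range(5):
                rows.append({"subject": s, "time": t,
                             "value": base + rng.normal(0, 1 + 0.3 * t)})
        df = pd.DataFrame(rows)
        aov = pg.rm_anova(data=df, dv="value", within="time",
                          subject="subject", correction=True)
        wide = df.pivot(index="subject", columns="time", values="value").to_numpy()
        assert stats.gg_epsilon(wide) == pytest.approx(
            float(aov["eps"].iloc[0]), abs=1e-6)

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(7)
        n_sim, hits = 150, 0
        for _ in range(n_sim):
            rows = []
            for g in ("A", "B"):
                for s in range(8):
                    base = rng.normal()
                    for t in range(4):
                        rows.append({"subject": f"{g}{s}", "group": g,
                                     "time": t, "value": base + rng.normal()})
            aov, _ = stats.rm_anova_gg(pd.DataFrame(rows), posthoc=False)
            p = float(aov.set_index("Source").loc["Interaction", "p_GG_corr"])
            hits += p < 0.05
        assert 0.01 <= hits / n_sim <= 0.12

    def test_bonferroni_posthoc_capped(self):
        rng = np.random.default_rng(8)
        rows = []
        for g in ("A", "B"):
            for s in range(6):
                for t in range(5):
                    rows.append({"subject": f"{g}{s}", "group": g, "time": t,
                                 "value": rng.normal()})
        _, ph = stats.rm_anova_gg(pd.DataFrame(rows))
        assert (ph["p_bonferroni"] <= 1.0).all()
        assert np.allclose(
            ph["p_bonferroni"],
            np.minimum(ph["p_uncorrected"] * len(ph), 1.0))
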