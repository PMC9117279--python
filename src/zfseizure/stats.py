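"""The study's statistical layer.

Authored here: Barnard's exact unconditional 2x2 test (nuisance-parameter
maximization on a fine grid with local refinement) and the percentile
bootstrap for difference-of-means estimation plots.  Standard tests are thin,
uniform wrappers over scipy (Fisher, Mann-Whitney, Wilcoxon, Kruskal-Wallis),
lifelines (Kaplan-Meier, log-rank) and pingouin (mixed-design repeated-
measures ANOVA with Greenhouse-Geisser correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

# ---------------------------------------------------------------------------
# Barnard exact unconditional test
# ---------------------------------------------------------------------------


def _statistic_matrix(n1: int, n2: int, statistic: str) -> np.ndarray:
    """T[k1, k2] for all 2x2 tables with margins (n1, n2).

    ``score``: pooled-variance standardized difference of proportions (the
    classical Z-pooled ordering); ``wald``: unpooled variance.  Tables with
    equal proportions get T = 0 (their standardization is 0/0).
    """
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    p1 = x1[:, None] / n1
    p2 = x2[None, :] / n2
    if statistic == "score":
        pp = (x1[:, None] + x2[None, :]) / (n1 + n2)
        var = pp * (1 - pp) * (1 / n1 + 1 / n2)
    elif statistic == "wald":
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    else:
        raise ValueError("statistic must be 'score' or 'wald'")
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (p1 - p2) / np.sqrt(var)
    T[p1 == p2] = 0.0
    T[np.isnan(T)] = 0.0
    return T


def _max_over_nuisance(mask: np.ndarray, n1: int, n2: int, grid_points: int) -> float:
    """sup over the common success probability of P(table in ``mask``)."""
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    m = mask.astype(float)

    def p_of(pis: np.ndarray) -> np.ndarray:
        pm1 = sps.binom.pmf(x1[None, :], n1, pis[:, None])
        pm2 = sps.binom.pmf(x2[None, :], n2, pis[:, None])
        return np.einsum("gi,ij,gj->g", pm1, m, pm2)

    # interior grid plus the degenerate endpoints (the sup can sit at pi -> 0/1,
    # where all mass lies on the all-failure / all-success table)
    pis = np.linspace(0.0, 1.0, grid_points + 2)
    vals = p_of(pis)
    best = float(vals.max())
    i = int(vals.argmax())
    # local refinement around the grid maximum (two zoom rounds)
    lo = pis[max(i - 1, 0)]
    hi = pis[min(i + 1, len(pis) - 1)]
    for _ in range(2):
        fine = np.linspace(lo, hi, 201)
        fv = p_of(fine)
        j = int(fv.argmax())
        best = max(best, float(fv.max()))
        lo = fine[max(j - 1, 0)]
        hi = fine[min(j + 1, 200)]
    # the supremum can sit at the boundary (degenerate tables)
    return min(best, 1.0)


def barnard_exact(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alternative: str = "two_sided",
    statistic: str = "score",
    grid_points: int = 2001,
) -> float:
    """Barnard's exact unconditional test for a 2x2 table (k1/n1 vs k2/n2).

    The p-value is the supremum over the common success probability of the
    total probability of tables whose ordering statistic is at least as
    extreme as observed.  ``alternative='one_sided'`` tests p1 > p2 when
    k1/n1 >= k2/n2 (and p1 < p2 otherwise); ``'two_sided'`` uses |T|.
    Deterministic; runtime well under a second for study-sized groups.

    For the fully separated 7/7 vs 0/7 design the one-sided p-value is
    analytically max_pi pi^7 (1-pi)^7 = 0.5^14 ~= 6.1e-5.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("require 0 <= k_i <= n_i")
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate margin: n1 and n2 must be positive")
    if grid_points < 1000:
        raise ValueError("grid_points must be >= 1000")
    T = _statistic_matrix(n1, n2, statistic)
    t_obs = T[k1, k2]
    eps = 1e-12
    if alternative == "one_sided":
        mask = T >= t_obs - eps if t_obs >= 0 else T <= t_obs + eps
    elif alternative == "two_sided":
        mask = np.abs(T) >= abs(t_obs) - eps
    else:
        raise ValueError("alternative must be 'one_sided' or 'two_sided'")
    return _max_over_nuisance(mask, n1, n2, grid_points)


# ---------------------------------------------------------------------------
# standard nonparametric tests (scipy wrappers)
# ---------------------------------------------------------------------------

_ALT = {"one_sided": "greater", "two_sided": "two-sided",
        "greater": "greater", "less": "less", "two-sided": "two-sided"}


def fisher_exact_2x2(k1: int, n1: int, k2: int, n2: int,
                     alternative: str = "two_sided"):
    """Fisher's exact test on successes/failures (k1/n1 vs k2/n2).

    Returns (odds_ratio, p).  ``one_sided`` maps to 'greater' for k1/n1.
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    res = sps.fisher_exact(table, alternative=_ALT[alternative])
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y, alternative: str = "two_sided"):
    """Mann-Whitney U; exact null distribution for small untied samples
    (scipy switches to the tie-corrected normal approximation otherwise)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if has_ties:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_ALT[alternative], method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y=None, alternative: str = "two_sided"):
    """Wilcoxon signed-rank test for paired samples (or differences)."""
    res = sps.wilcoxon(x, y, alternative=_ALT[alternative])
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups):
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def kaplan_meier(data: pd.DataFrame):
    """Product-limit survivor estimate.

    ``data`` needs columns ``time`` (h) and ``event`` (1 = death).  Returns a
    DataFrame with columns ``time, survival`` (step function evaluated at the
    event times, S(0) = 1 prepended).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], event_observed=data["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy()})


def logrank(data1: pd.DataFrame, data2: pd.DataFrame):
    """Log-rank (Mantel-Cox) test between two survival samples: (chi2, p)."""
    from lifelines.statistics import logrank_test

    res = logrank_test(
        data1["time"], data2["time"],
        event_observed_A=data1["event"], event_observed_B=data2["event"],
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# estimation statistics
# ---------------------------------------------------------------------------


@dataclass
class EstimationResult:
    difference: float       # mean(y) - mean(x)
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_diff_means(
    x, y, n_boot: int = 10_000, seed: int = 0, ci: float = 0.95
) -> EstimationResult:
    """Percentile-bootstrap CI for mean(y) - mean(x), deterministic per seed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    bx = rng.integers(0, len(x), size=(n_boot, len(x)))
    by = rng.integers(0, len(y), size=(n_boot, len(y)))
    diffs = y[by].mean(axis=1) - x[bx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return EstimationResult(
        difference=float(y.mean() - x.mean()),
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------


def gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x time measurement matrix."""
    S = np.cov(wide, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (row_means ** 2).sum() + k ** 2 * grand ** 2)
    if den <= 0:
        return 1.0
    return float(min(num / den, 1.0))


def rm_anova_gg(data: pd.DataFrame, posthoc: bool = True):
    """Two-way (group x time) repeated-measures ANOVA, time repeated.

    ``data`` is long format with columns ``subject, group, time, value``.
    Returns ``(anova_table, posthoc_table)``: the ANOVA table carries F,
    Greenhouse-Geisser epsilon and GG-corrected p for the within and
    interaction effects; the post-hoc table holds per-time-bin two-sample
    comparisons with Bonferroni-adjusted p (p * n_bins, capped at 1).
    """
    import pingouin as pg

    aov = pg.mixed_anova(
        data=data, dv="value", within="time", subject="subject",
        between="group", correction=True,
    )
    # pingouin corrects only the within effect; apply the same epsilon to the
    # group x time interaction (both share the repeated-measures error term)
    aov = aov.set_index("Source")
    if "eps" in aov.columns and "Interaction" in aov.index:
        eps = float(aov.loc["time", "eps"])
        aov.loc["Interaction", "eps"] = eps
        f_int = float(aov.loc["Interaction", "F"])
        df1 = float(aov.loc["Interaction", "DF1"]) * eps
        df2 = float(aov.loc["Interaction", "DF2"]) * eps
        aov.loc["Interaction", "p_GG_corr"] = float(sps.f.sf(f_int, df1, df2))
    aov = aov.reset_index()
    ph = None
    if posthoc:
        times = sorted(data["time"].unique())
        groups = sorted(data["group"].unique())
        if len(groups) != 2:
            raise ValueError("per-bin post-hoc comparisons need exactly 2 groups")
        rows = []
        for t in times:
            a = data[(data["time"] == t) & (data["group"] == groups[0])]["value"]
            b = data[(data["time"] == t) & (data["group"] == groups[1])]["value"]
            tt = sps.ttest_ind(a, b)
            rows.append({
                "time": t, "t": float(tt.statistic), "p_uncorrected": float(tt.pvalue),
                "p_bonferroni": min(float(tt.pvalue) * len(times), 1.0),
            })
        ph = pd.DataFrame(rows)
    return aov, ph


# ---------------------------------------------------------------------------
# simple post-hoc helpers
# ---------------------------------------------------------------------------


def bonferroni(pvals) -> np.ndarray:
    return np.minimum(np.asarray(pvals, dtype=float) * len(pvals), 1.0)


def dunn_pairwise(groups: dict):
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    Returns a DataFrame of pairwise z statistics and Bonferroni-adjusted p.
    """
    names = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], float) for g in names])
    ranks = sps.rankdata(all_vals)
    n = len(all_vals)
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[i:i + k].mean()
        sizes[g] = k
        i += k
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (n - 1))
    rows = []
    from itertools import combinations as _comb

    n_pairs = len(names) * (len(names) - 1) // 2
    for g1, g2 in _comb(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[g1] + 1 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": float(z),
                     "p_uncorrected": float(p),
                     "p_bonferroni": min(float(p) * n_pairs, 1.0)})
    return pd.DataFrame(rows)
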