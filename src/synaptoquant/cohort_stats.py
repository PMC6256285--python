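"""Cohort construction and the statistical test battery.

Cumulative-distribution comparisons are run on cohorts built by sampling an
equal number of observations per cell (so no cell dominates the pooled
distribution), compared with a two-sample Kolmogorov-Smirnov test at
alpha = 0.005; more than two groups go through Kruskal-Wallis with Dunn's
corrected post hoc z-tests. Mean comparisons use Wilcoxon matched-pairs
(paired), Mann-Whitney (unpaired) or two-way ANOVA with Sidak-corrected
within-group contrasts (factorial), at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

KS_ALPHA = 0.005
MEAN_ALPHA = 0.05


@dataclass
class Cohort:
    """Pooled observations with per-value cell provenance."""

    values: np.ndarray
    cell_ids: np.ndarray
    n_per_cell: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.values.shape != self.cell_ids.shape:
            raise ValueError("values and cell_ids must align")
        _, counts = np.unique(self.cell_ids, return_counts=True)
        if counts.size and not np.all(counts == self.n_per_cell):
            raise ValueError("every cell must contribute exactly n_per_cell values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class TestReport:
    test: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    details: dict | None = None


def sample_cohort(
    per_cell_values: dict,
    n_per_cell: int,
    seed: int | None = None,
    replace: bool = False,
) -> Cohort:
    """Sample ``n_per_cell`` values from each cell (without replacement).

    Cell order is fixed by sorted cell id so the cohort is reproducible from
    the seed alone; a cell with fewer than ``n_per_cell`` values is an error
    naming the offending cell.
    """
    rng = np.random.default_rng(seed)
    values, cells = [], []
    for cell in sorted(per_cell_values):
        v = np.asarray(per_cell_values[cell], dtype=float)
        if not replace and v.size < n_per_cell:
            raise ValueError(
                f"cell {cell!r} has only {v.size} values; {n_per_cell} required"
            )
        pick = rng.choice(v, size=n_per_cell, replace=replace)
        values.append(pick)
        cells.append(np.full(n_per_cell, cell))
    return Cohort(
        values=np.concatenate(values) if values else np.empty(0),
        cell_ids=np.concatenate(cells) if cells else np.empty(0),
        n_per_cell=n_per_cell,
        seed=seed,
    )


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, Cohort) else np.asarray(x, dtype=float)


def compare_distributions(*groups, alpha: float = KS_ALPHA) -> TestReport:
    """Two-sample KS for two groups; Kruskal-Wallis + Dunn for more.

    Accepts Cohorts or plain arrays. Two identical constant samples take the
    degenerate p = 1 path rather than erroring.
    """
    arrs = [_as_values(g) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("groups must be non-empty")
    if len(arrs) == 2:
        a, b = arrs
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return TestReport("ks_2samp", 0.0, 1.0, False, alpha)
        res = stats.ks_2samp(a, b)
        return TestReport(
            "ks_2samp", float(res.statistic), float(res.pvalue), res.pvalue < alpha, alpha
        )
    kw = stats.kruskal(*arrs)
    dunn = dunn_posthoc(arrs, alpha=alpha)
    return TestReport(
        "kruskal_dunn",
        float(kw.statistic),
        float(kw.pvalue),
        kw.pvalue < alpha,
        alpha,
        details={"dunn": dunn},
    )


def dunn_posthoc(groups, alpha: float = MEAN_ALPHA) -> list[dict]:
    """Dunn's z-tests on Kruskal-Wallis rank sums, Bonferroni-adjusted.

    Mean ranks come from the pooled ranking (with tie correction); two-sided
    p-values are multiplied by the number of pairwise comparisons, the
    adjustment conventionally bundled with Dunn's test.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrs)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrs]
    edges = np.cumsum([0, *sizes])
    mean_ranks = [ranks[e0:e1].mean() for e0, e1 in zip(edges[:-1], edges[1:])]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    m = len(arrs) * (len(arrs) - 1) // 2
    out = []
    for i, j in combinations(range(len(arrs)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        out.append(
            {"pair": (i, j), "z": float(z), "p_adj": float(p), "significant": p < alpha}
        )
    return out


def paired_tests(before, after=None, design: str = "paired", alpha: float = MEAN_ALPHA):
    """Dispatch the mean-comparison test for a given design.

    * ``paired``: Wilcoxon matched-pairs signed-rank on aligned arrays;
    * ``unpaired``: Mann-Whitney U;
    * ``factorial``: two-way ANOVA (genotype x treatment) on a tidy
      DataFrame passed as ``before`` with columns ``value``, ``genotype``,
      ``treatment``, followed by Sidak-corrected within-genotype contrasts.
    """
    if design == "factorial":
        return factorial_anova(before, alpha=alpha)
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if design == "paired":
        if a.shape != b.shape:
            raise ValueError("paired samples must be aligned (same length/order)")
        if np.all(a == b):
            return TestReport("wilcoxon", 0.0, 1.0, False, alpha)
        res = stats.wilcoxon(a, b)
        return TestReport(
            "wilcoxon", float(res.statistic), float(res.pvalue), res.pvalue < alpha, alpha
        )
    if design == "unpaired":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestReport(
            "mannwhitneyu", float(res.statistic), float(res.pvalue), res.pvalue < alpha, alpha
        )
    raise ValueError(f"unknown design {design!r}")


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment of one of m p-values."""
    return float(1.0 - (1.0 - min(p, 1.0)) ** m)


def factorial_anova(
    df: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "treatment",
    alpha: float = MEAN_ALPHA,
) -> dict:
    """Two-way ANOVA plus Sidak-corrected within-``factor_a`` contrasts.

    The post hoc compares the two ``factor_b`` levels within each level of
    ``factor_a`` (paired t when a ``cell`` column aligns them, Welch t
    otherwise), Sidak-adjusting across the levels of ``factor_a``.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = df.rename(columns={value: "_v", factor_a: "_a", factor_b: "_b"})
    model = ols("_v ~ C(_a) * C(_b)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    levels_a = sorted(d["_a"].unique())
    levels_b = sorted(d["_b"].unique())
    posthoc = []
    if len(levels_b) == 2:
        for la in levels_a:
            sub = d[d["_a"] == la]
            g0 = sub[sub["_b"] == levels_b[0]]
            g1 = sub[sub["_b"] == levels_b[1]]
            if "cell" in sub.columns and len(g0) == len(g1):
                x0 = g0.sort_values("cell")["_v"].to_numpy()
                x1 = g1.sort_values("cell")["_v"].to_numpy()
                t = stats.ttest_rel(x0, x1)
            else:
                t = stats.ttest_ind(
                    g0["_v"].to_numpy(), g1["_v"].to_numpy(), equal_var=False
                )
            p_adj = sidak_adjust(float(t.pvalue), len(levels_a))
            posthoc.append(
                {
                    "level": la,
                    "t": float(t.statistic),
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return {"anova": table, "posthoc": posthoc, "alpha": alpha}
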