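"""Inferential layer: ANOVA + Tukey HSD, block-adjusted predicted means
with approximate pairwise t-tests, and the tolerance-vs-ion regressions.

The genotype x salinity analysis uses a fixed-effects linear model with
a replicate block term and homoscedastic residuals.  Pairs of predicted
means are compared with an approximate t statistic built from the
predictions' standard errors; when per-cell variances are flagged
unequal, each prediction's variance is replaced by the average variance
of the pairwise differences it is involved in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PredictedMeans",
    "PairwiseComparison",
    "anova_tukey",
    "predicted_means",
    "approx_t_pvalue",
    "pairwise_comparisons",
    "regress_st_on_ion",
    "correlate",
]


@dataclass(frozen=True)
class PredictedMeans:
    """Least-squares cell means with standard errors and Wald F-tests."""

    table: pd.DataFrame          # columns: cell labels, mean, se, n
    wald: pd.DataFrame           # F-tests for main effects and interaction
    residual_df: int


@dataclass(frozen=True)
class PairwiseComparison:
    cell_a: str
    cell_b: str
    difference: float
    t_value: float
    p_value: float
    adjusted_p: float | None = None


def anova_tukey(
    data: pd.DataFrame,
    response: str,
    factor: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[PairwiseComparison]]:
    """One-way ANOVA with Tukey HSD all-pairs comparisons.

    Adjusted p-values come from the studentized-range distribution.
    Requires at least two groups with two observations each.
    """
    groups = data.groupby(factor)[response]
    if groups.ngroups < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 observations: {bad}")
    model = smf.ols(f"Q('{response}') ~ C(Q('{factor}'))", data=data).fit()
    table = sm.stats.anova_lm(model, typ=1)
    tk = pairwise_tukeyhsd(data[response], data[factor], alpha=alpha)
    comparisons = []
    for (a, b), meandiff, p_adj in zip(
            combinations(tk.groupsunique, 2), tk.meandiffs, tk.pvalues):
        comparisons.append(PairwiseComparison(
            cell_a=str(a), cell_b=str(b), difference=float(meandiff),
            t_value=float("nan"), p_value=float(p_adj), adjusted_p=float(p_adj)))
    return table, comparisons


def predicted_means(
    data: pd.DataFrame,
    response: str,
    genotype: str = "genotype",
    treatment: str = "treatment",
    replicate: str = "replicate",
) -> PredictedMeans:
    """Cell means and SEs from a genotype*treatment + replicate-block model.

    On a balanced complete design the predicted means equal the raw cell
    means.  Wald F-tests (type II sums of squares, fixed-model residual
    df) are reported for both main effects and their interaction.
    """
    counts = data.groupby([genotype, treatment]).size()
    full = pd.MultiIndex.from_product(
        [data[genotype].unique(), data[treatment].unique()])
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cell(s): {list(missing)[:3]}")
    formula = (f"Q('{response}') ~ C(Q('{genotype}')) * C(Q('{treatment}'))"
               f" + C(Q('{replicate}'))")
    model = smf.ols(formula, data=data).fit()
    wald = sm.stats.anova_lm(model, typ=2)

    reps = sorted(data[replicate].unique())
    rows = []
    for (g, t), n in counts.items():
        # average the prediction over replicate blocks
        grid = pd.DataFrame({genotype: g, treatment: t, replicate: reps})
        pred = model.get_prediction(grid)
        w = np.full(len(reps), 1.0 / len(reps))
        mean = float(w @ pred.predicted_mean)
        # var of the averaged prediction: (w'X) Cov(beta) (w'X)'
        Xg = dmatrix(model.model.data.design_info, grid,
                     return_type="dataframe").to_numpy()
        c = w @ Xg
        se = float(np.sqrt(c @ model.cov_params().to_numpy() @ c))
        rows.append({"genotype": g, "treatment": t,
                     "cell": f"{g}:{t}", "mean": mean, "se": se, "n": int(n)})
    table = pd.DataFrame(rows)
    return PredictedMeans(table=table, wald=wald,
                          residual_df=int(model.df_resid))


def approx_t_pvalue(
    mean_a: float,
    se_a: float,
    mean_b: float,
    se_b: float,
    df: float | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> PairwiseComparison:
    """Approximate t-test for a difference of two predicted means.

    t = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2), with a two-sided
    p-value from the standard normal reference by default, or from a t
    distribution when ``df`` is given.
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be >= 0")
    denom = float(np.hypot(se_a, se_b))
    if denom == 0:
        raise ValueError("both standard errors are zero")
    t = (mean_a - mean_b) / denom
    if df is None:
        p = 2.0 * sps.norm.sf(abs(t))
    else:
        p = 2.0 * sps.t.sf(abs(t), df)
    return PairwiseComparison(cell_a=labels[0], cell_b=labels[1],
                              difference=float(mean_a - mean_b),
                              t_value=float(t), p_value=float(p))


def pairwise_comparisons(
    means: pd.DataFrame,
    *,
    unequal_variance: bool = False,
    df: float | None = None,
) -> list[PairwiseComparison]:
    """All-pairs approximate t-tests on a predicted-means table.

    With ``unequal_variance`` each prediction's variance is replaced by
    the average variance of the pairwise differences that prediction is
    involved in, before forming the test statistics.
    """
    cells = means["cell"].tolist()
    mu = means["mean"].to_numpy(dtype=float)
    var = means["se"].to_numpy(dtype=float) ** 2
    if unequal_variance:
        k = len(cells)
        if k < 2:
            raise ValueError("need at least two cells")
        adj = np.empty(k)
        for i in range(k):
            d_vars = [var[i] + var[j] for j in range(k) if j != i]
            adj[i] = 0.5 * float(np.mean(d_vars))
        var = adj
    out = []
    for i, j in combinations(range(len(cells)), 2):
        out.append(approx_t_pvalue(mu[i], float(np.sqrt(var[i])),
                                   mu[j], float(np.sqrt(var[j])),
                                   df=df, labels=(cells[i], cells[j])))
    return out


def regress_st_on_ion(st, ion) -> dict[str, float]:
    """OLS of salinity tolerance on a genotype-level ion concentration.

    Returns slope, intercept, r_squared (squared Pearson correlation)
    and the two-sided p-value of the slope.
    """
    st = np.asarray(st, dtype=float)
    ion = np.asarray(ion, dtype=float)
    if st.size != ion.size or st.size < 3:
        raise ValueError("need >= 3 paired genotype-level points")
    if np.ptp(ion) == 0:
        raise ValueError("constant ion concentrations: slope undefined")
    res = sps.linregress(ion, st)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p_value": float(res.pvalue)}


def correlate(a, b) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = sps.pearsonr(a, b)
    return float(r ** 2), float(p)
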