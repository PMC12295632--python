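"""Statistical primitives shared by the behavioral and proteomics pipelines.

Welch's unequal-variance t-test is the default two-group comparison (the
right choice for n = 2 LFQ replicates with heterogeneous variances);
Student's pooled-variance t is available behind a flag. Multiple testing
uses Benjamini-Hochberg step-up adjusted p-values. The factorial
group x light-condition comparison uses a balanced two-way ANOVA with
interaction followed by Tukey's HSD over cell means. Gene-set
over-representation uses the exact hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateVarianceError, UnbalancedDesignError, ValidationError

__all__ = [
    "TestResult",
    "AnovaTable",
    "welch_t",
    "bh_adjust",
    "two_way_anova",
    "tukey_hsd",
    "hypergeom_enrich_p",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    tails: str = "two"


@dataclass(frozen=True)
class AnovaTable:
    """Sum-of-squares decomposition of a balanced two-factor design."""

    table: pd.DataFrame  # index: factor_a, factor_b, interaction, residual

    @property
    def total_ss(self) -> float:
        return float(self.table["sum_sq"].sum())

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])


def welch_t(a, b, *, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t-test; Welch by default, Student if equal_var.

    Raises DegenerateVarianceError when both samples have zero variance —
    the caller decides what to do with such rows (the DE pipeline reports
    them separately rather than assigning p = 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("both samples have zero variance")
    res = st.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    q(i) = min over j >= i (sorted) of p(j)*m/j, capped at 1. Output is
    elementwise >= input and order-preserving; it is not idempotent (the
    adjusted values are themselves valid inputs but re-adjusting inflates
    them further).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def _check_balanced(factor_a: np.ndarray, factor_b: np.ndarray) -> pd.DataFrame:
    cells = pd.crosstab(pd.Series(factor_a, name="a"), pd.Series(factor_b, name="b"))
    counts = cells.to_numpy()
    if counts.size == 0 or (counts != counts.flat[0]).any():
        raise UnbalancedDesignError(
            f"unbalanced design (cell counts {sorted(set(counts.ravel().tolist()))}); "
            "only balanced designs are supported"
        )
    if counts.flat[0] < 2:
        raise UnbalancedDesignError("need at least 2 replicates per cell")
    return cells


def two_way_anova(values, factor_a, factor_b) -> AnovaTable:
    """Balanced two-way ANOVA with interaction (type I = II = III under balance).

    Degenerate all-equal data yields F = 0, p = 1 for every effect rather
    than NaN, so downstream reports stay well-defined.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (len(values) == len(factor_a) == len(factor_b)):
        raise ValidationError("values and factor labels must have equal length")
    _check_balanced(factor_a, factor_b)
    total_ss = float(np.sum((values - values.mean()) ** 2))
    if total_ss <= 1e-12 * max(1.0, float(np.mean(values**2))) * len(values):
        # No variance at all: every effect is exactly null.
        cells = len(np.unique(factor_a)) , len(np.unique(factor_b))
        dfa, dfb = cells[0] - 1, cells[1] - 1
        table = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "df": [dfa, dfb, dfa * dfb, len(values) - 1 - dfa - dfb - dfa * dfb],
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=["factor_a", "factor_b", "interaction", "residual"],
        )
        return AnovaTable(table=table)
    df = pd.DataFrame({"y": values, "a": factor_a.astype(str), "b": factor_b.astype(str)})
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {"C(a)": "factor_a", "C(b)": "factor_b", "C(a):C(b)": "interaction", "Residual": "residual"}
    aov.index = [rename[i] for i in aov.index]
    out = aov.rename(columns={"PR(>F)": "p"})[["sum_sq", "df", "F", "p"]]
    # Zero-variance data: define F = 0, p = 1 for effects with zero SS.
    for effect in ("factor_a", "factor_b", "interaction"):
        if not np.isfinite(out.loc[effect, "F"]):
            if out.loc[effect, "sum_sq"] <= 1e-12:
                out.loc[effect, ["F", "p"]] = [0.0, 1.0]
    return AnovaTable(table=out)


def tukey_hsd(values, cell_labels) -> pd.DataFrame:
    """Tukey HSD over the means of labelled cells (balanced design).

    Returns one row per unordered cell pair with the mean difference and
    the studentized-range adjusted p (symmetric in pair order). With
    exactly two cells this reduces to the pooled-variance t-test
    (q = |t|*sqrt(2)).
    """
    values = np.asarray(values, dtype=float)
    cell_labels = np.asarray(cell_labels)
    labels = sorted(pd.unique(cell_labels).tolist())
    if len(labels) < 2:
        raise ValidationError("Tukey HSD needs at least 2 cells")
    groups = [values[cell_labels == lab] for lab in labels]
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise UnbalancedDesignError("Tukey HSD here supports balanced cells only")
    if sizes.pop() < 2:
        raise ValidationError("need at least 2 observations per cell")
    if np.ptp(values) == 0:
        # Constant data: no differences anywhere, adjusted p = 1 for all pairs.
        rows = [
            {"cell_1": labels[i], "cell_2": labels[j], "mean_diff": 0.0, "p_adj": 1.0}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return pd.DataFrame(rows, columns=["cell_1", "cell_2", "mean_diff", "p_adj"])
    res = st.tukey_hsd(*groups)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "cell_1": labels[i],
                    "cell_2": labels[j],
                    "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_adj": float(min(res.pvalue[i, j], 1.0)),
                }
            )
    return pd.DataFrame(rows, columns=["cell_1", "cell_2", "mean_diff", "p_adj"])


def hypergeom_enrich_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P[X >= k]: k hits in a query of size n
    against a term of size K within a background of size N."""
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValidationError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    return float(st.hypergeom.sf(k - 1, N, K, n))
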