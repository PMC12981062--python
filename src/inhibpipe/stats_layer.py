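"""Group-level statistics applied to pipeline outputs.

The battery mirrors standard practice for this kind of dataset: unpaired
two-tailed equal-variance t-tests for two-group contrasts, one- and
two-way ANOVA on pooled data, a random-intercept mixed model for
repeated-measures input-output curves (which tolerates missing cells),
and Sidak correction for multiple comparisons. The significance level is
0.05 throughout; statistical units are cells for electrophysiology and
animals for imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = ["GroupComparison", "ttest_unpaired", "anova", "sidak_adjust"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """One hypothesis test: statistic, degrees of freedom, p-value."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_direction: float = 0.0
    term: str = ""
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def ttest_unpaired(group_a, group_b) -> GroupComparison:
    """Classical two-sample equal-variance t-test, two-tailed.

    With zero variance in both groups and equal means the comparison is
    vacuous and reported as t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return GroupComparison("t_unpaired", 0.0, (float(df),), 1.0, 0.0)
        return GroupComparison(
            "t_unpaired", float("inf"), (float(df),), 0.0,
            float(np.sign(np.mean(a) - np.mean(b))),
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        "t_unpaired", float(t), (float(df),), float(p),
        float(np.sign(np.mean(a) - np.mean(b))),
    )


def _check_full_rank(table: pd.DataFrame, formula: str) -> None:
    import patsy

    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name a column whose removal restores full rank
        for j, name in enumerate(X.columns):
            reduced = np.delete(X.values, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"rank-deficient design: term '{name}' is aliased")
        raise ValueError("rank-deficient design")


def _mixed_repeated(
    table: pd.DataFrame, dv: str, between: str, within: str, subject: str
) -> list[GroupComparison]:
    """Random-intercept mixed model for genotype (between) x intensity (within).

    Fixed effects use sum-to-zero coding so Wald tests of each term are
    type-III main effects / interaction; fitting is by REML. Denominator
    degrees of freedom use the containment rule: the between factor is
    tested against subjects, the within factor and the interaction
    against the subject x within stratum — exact for balanced data and a
    conservative approximation under missingness.
    """
    data = table.dropna(subset=[dv]).copy()
    formula = f"{dv} ~ C({between}, Sum) * C({within}, Sum)"
    _check_full_rank(data, formula)
    model = smf.mixedlm(formula, data, groups=data[subject])
    fit = model.fit(reml=True, method=["lbfgs", "powell"])

    design_info = model.data.design_info
    n_subj = data[subject].nunique()
    a = data[between].nunique()
    b = data[within].nunique()
    df2_between = max(1.0, n_subj - a)
    df2_within = max(1.0, (n_subj - a) * (b - 1))

    out = []
    # the params vector appends variance components after the fixed effects;
    # contrasts must span the full vector
    k_all = len(fit.params)
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(sl.start, sl.stop))
        contrast = np.zeros((len(idx), k_all))
        for row, j in enumerate(idx):
            contrast[row, j] = 1.0
        wald = fit.wald_test(contrast, scalar=False)
        q = len(idx)
        f_stat = float(np.squeeze(wald.statistic)) / q
        df2 = df2_between if within not in term else df2_within
        p = float(stats.f.sf(f_stat, q, df2))
        out.append(
            GroupComparison("mixed_repeated_F", f_stat, (float(q), df2), p,
                            term=term)
        )
    return out


def anova(
    table: pd.DataFrame,
    design: str,
    dv: str = "value",
    factors: tuple[str, ...] = ("genotype",),
    subject: str = "cell_id",
) -> list[GroupComparison]:
    """F tests per main effect (and interaction) for the stated design.

    Parameters
    ----------
    table
        Long-format data: one row per observation.
    design
        ``one_way`` (one between factor), ``two_way`` (two crossed
        factors with interaction, type-II sums of squares), or
        ``mixed_repeated`` (factors = (between, within), random intercept
        per ``subject``; unbalanced / missing cells permitted).
    """
    if design == "one_way":
        (factor,) = factors
        formula = f"{dv} ~ C({factor})"
        _check_full_rank(table, formula)
        fit = smf.ols(formula, data=table).fit()
        tab = anova_lm(fit, typ=1)
        row = tab.iloc[0]
        return [
            GroupComparison(
                "one_way_F", float(row["F"]),
                (float(row["df"]), float(tab.iloc[-1]["df"])),
                float(row["PR(>F)"]), term=factor,
            )
        ]
    if design == "two_way":
        fa, fb = factors
        formula = f"{dv} ~ C({fa}) * C({fb})"
        _check_full_rank(table, formula)
        fit = smf.ols(formula, data=table).fit()
        tab = anova_lm(fit, typ=2)
        df_resid = float(tab.loc["Residual", "df"])
        out = []
        for term in tab.index:
            if term == "Residual":
                continue
            row = tab.loc[term]
            out.append(
                GroupComparison(
                    "two_way_F", float(row["F"]),
                    (float(row["df"]), df_resid), float(row["PR(>F)"]),
                    term=term,
                )
            )
        return out
    if design == "mixed_repeated":
        between, within = factors
        return _mixed_repeated(table, dv, between, within, subject)
    raise ValueError(f"unknown design '{design}'")


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak-adjusted p-values: p_adj = 1 - (1 - p)^m, clipped at 1.

    ``m`` defaults to the number of comparisons supplied and must be at
    least that many. Uniformly no larger than the Bonferroni adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= the number of p-values")
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)
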