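"""Group-level statistics: summary t tests, Bonferroni, factorial models.

The layer mirrors the statistical toolbox of a behavioral-ephys study:

* :func:`t_from_summaries` — two-sample t computed from published-style
  summaries (mean ± SEM, n), pooled (classical Student) by default or
  Welch by flag.
* :func:`bonferroni` — multiplicity adjustment for post hoc families.
* :func:`fit_factorial` — factorial / repeated-measures designs.  The
  numerical engines are delegated: pure between-subject designs go to an
  ordinary-least-squares ANOVA, a one-between × one-within design goes
  to a classical mixed ANOVA (exact F tests), and general designs with a
  random intercept per mouse (e.g., electrode-level measures nested in
  mice) go to a linear mixed model with Wald term tests.
* :func:`pearson_corr` — two-tailed Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class GroupSummary:
    """Published-style group summary: mean ± SEM with group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sem < 0:
            raise ValueError("SEM must be nonnegative")

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sem=float(sstats.sem(x)), n=x.size)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    adjusted_p: float | None = None


def t_from_summaries(
    a: GroupSummary, b: GroupSummary, variant: str = "pooled"
) -> TestResult:
    """Unpaired two-tailed two-sample t test from group summaries.

    Group SDs are recovered as ``sem * sqrt(n)``.  The pooled variant is
    the classical Student test with ``df = n_a + n_b - 2``; ``welch``
    uses the Welch–Satterthwaite approximation.
    """
    sd_a = a.sem * np.sqrt(a.n)
    sd_b = b.sem * np.sqrt(b.n)
    va, vb = sd_a**2, sd_b**2
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    elif variant == "welch":
        se2a, se2b = va / a.n, vb / b.n
        se = np.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (a.n - 1) + se2b**2 / (b.n - 1)
        )
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    if se == 0.0:
        t = 0.0 if a.mean == b.mean else np.inf * np.sign(a.mean - b.mean)
    else:
        t = (a.mean - b.mean) / se
    p = 2.0 * sstats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return TestResult(statistic=float(t), df=float(df), p=float(p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)``, m defaulting to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


def _terms(factors: list[str], max_order: int | None = None) -> list[str]:
    """All main effects and interactions, e.g. ['a', 'b', 'a:b']."""
    from itertools import combinations

    max_order = max_order or len(factors)
    out = []
    for k in range(1, max_order + 1):
        out.extend(":".join(c) for c in combinations(factors, k))
    return out


def fit_factorial(
    table: pd.DataFrame,
    response: str,
    between: list[str] | None = None,
    within: list[str] | None = None,
    subject: str | None = None,
) -> pd.DataFrame:
    """Fit a factorial design and return per-term tests.

    Returns a DataFrame with columns (term, statistic, df1, df2, p).
    Dispatch:

    * no ``within`` factors and no ``subject`` — OLS ANOVA (type II);
    * exactly one ``between`` and one ``within`` factor with a subject —
      classical mixed-design ANOVA (exact F tests);
    * anything else with a subject — linear mixed model with a random
      intercept per subject and Wald F tests per term.  This is the route
      for electrode-level measures (three electrodes nested per mouse)
      and the drug × virus × genotype designs.

    Raises on rank-deficient designs or an all-missing response.
    """
    between = list(between or [])
    within = list(within or [])
    factors = between + within
    if not factors:
        raise ValueError("need at least one factor")
    data = table.dropna(subset=[response]).copy()
    if data.empty:
        raise ValueError("response is all-missing")

    if not within and subject is None:
        return _fit_ols_anova(data, response, between)
    if subject is None:
        raise ValueError("within-subject factors require a subject column")
    if len(between) == 1 and len(within) == 1:
        return _fit_mixed_anova(data, response, between[0], within[0], subject)
    return _fit_lmm(data, response, factors, subject)


def _fit_ols_anova(data: pd.DataFrame, response: str, factors: list[str]) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rhs = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    aov = sm.stats.anova_lm(model, typ=2)
    rows = []
    resid_df = float(aov.loc["Residual", "df"])
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        term = name.replace("C(", "").replace(")", "")
        rows.append(
            {
                "term": term,
                "statistic": float(row["F"]),
                "df1": float(row["df"]),
                "df2": resid_df,
                "p": float(row["PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)


def _fit_mixed_anova(
    data: pd.DataFrame, response: str, between: str, within: str, subject: str
) -> pd.DataFrame:
    import pingouin as pg

    aov = pg.mixed_anova(
        data=data, dv=response, between=between, within=within, subject=subject
    )
    rows = []
    for _, row in aov.iterrows():
        term = row["Source"].replace(" * ", ":").replace("Interaction", f"{between}:{within}")
        rows.append(
            {
                "term": term,
                "statistic": float(row["F"]),
                "df1": float(row["DF1"]),
                "df2": float(row["DF2"]),
                "p": float(row["p_unc"]),
            }
        )
    return pd.DataFrame(rows)


def _fit_lmm(
    data: pd.DataFrame, response: str, factors: list[str], subject: str
) -> pd.DataFrame:
    import statsmodels.formula.api as smf

    rhs = " * ".join(f"C({f})" for f in factors)
    model = smf.mixedlm(f"{response} ~ {rhs}", data=data, groups=data[subject])
    try:
        fit = model.fit(reml=True)
    except np.linalg.LinAlgError:
        fit = model.fit(reml=True, method="powell")
    design_info = fit.model.data.design_info
    rows = []
    for term in design_info.terms:
        if not term.factors:  # intercept
            continue
        sl = design_info.term_slices[term]
        k = fit.fe_params.index[sl]
        contrast = np.zeros((len(k), len(fit.fe_params)))
        for i, name in enumerate(k):
            contrast[i, list(fit.fe_params.index).index(name)] = 1.0
        # pad for random-effect params in the full covariance
        full = np.zeros((contrast.shape[0], len(fit.params)))
        full[:, : contrast.shape[1]] = contrast
        wt = fit.wald_test(full, scalar=False)
        stat = float(np.squeeze(wt.statistic)) / contrast.shape[0]
        df1 = contrast.shape[0]
        df2 = float(data[subject].nunique() - len(fit.fe_params))
        df2 = max(df2, 1.0)
        p = float(sstats.f.sf(stat, df1, df2))
        rows.append(
            {
                "term": term.name().replace("C(", "").replace(")", ""),
                "statistic": stat,
                "df1": float(df1),
                "df2": df2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def tukey_pairwise(data: pd.DataFrame, response: str, group: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized-range machinery."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(data[response], data[group])
    return pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )


def pearson_corr(x, y) -> TestResult:
    """Two-tailed Pearson correlation (e.g., theta power vs investigation)."""
    r, p = sstats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return TestResult(statistic=float(r), df=float(len(np.asarray(x)) - 2), p=float(p))
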