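"""Group-comparison statistics used throughout the study pattern.

Two-group comparisons use an unpaired equal-variance t-test with an
explicit normality gate (Shapiro-Wilk per group at alpha = 0.05) that
switches to the Mann-Whitney U test; the gate decision is always reported.
Factorial designs use two-way ANOVA (Type II sums of squares by default)
with a mixed (one within-subject factor) variant, and Holm-Sidak step-down
adjustment for post hoc pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm  # noqa: F401  (formula backend registration)
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import ConfigurationError, InvalidSpecError


@dataclass(frozen=True)
class TwoGroupResult:
    test: str                    # "t" or "mannwhitney"
    statistic: float
    pvalue: float
    normality_p_a: float
    normality_p_b: float
    used_nonparametric: bool
    significant: bool
    alpha: float = 0.05


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p; degenerate inputs are treated as non-normal (p = 0)."""
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def compare_two_groups(a, b, force: str | None = None, alpha: float = 0.05,
                       normality_alpha: float = 0.05) -> TwoGroupResult:
    """Unpaired two-group comparison with a non-parametric fallback.

    ``force`` overrides the gate ("t" or "mannwhitney").  Ties of two
    zero-variance groups are resolved by definition: equal means give
    statistic 0 / p 1, distinct means a degenerate p of 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidSpecError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidSpecError("groups must contain finite values")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if force is None:
        nonparam = (pa < normality_alpha) or (pb < normality_alpha)
    elif force in ("t", "mannwhitney"):
        nonparam = force == "mannwhitney"
    else:
        raise ConfigurationError(f"unknown test {force!r}")

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = a[0] == b[0]
        return TwoGroupResult(test="t" if not nonparam else "mannwhitney",
                              statistic=0.0, pvalue=1.0 if same else 0.0,
                              normality_p_a=pa, normality_p_b=pb,
                              used_nonparametric=nonparam,
                              significant=not same, alpha=alpha)
    if nonparam:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mannwhitney"
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "t"
    stat, p = float(res.statistic), float(res.pvalue)
    return TwoGroupResult(test=name, statistic=stat, pvalue=p,
                          normality_p_a=pa, normality_p_b=pb,
                          used_nonparametric=nonparam,
                          significant=p < alpha, alpha=alpha)


# ------------------------------------------------------------------ ANOVA
@dataclass
class AnovaResult:
    """F table of a two-way design; one row per effect."""

    table: pd.DataFrame          # index: effect; columns: F, p, (df, sum_sq)
    repeated: bool = False
    details: dict = field(default_factory=dict)

    def effect(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["F"]), float(row["p"])


def two_way_anova(df: pd.DataFrame, dv: str, factor_a: str, factor_b: str,
                  repeated: bool = False, subject: str | None = None,
                  ss_type: int = 2) -> AnovaResult:
    """Two-way ANOVA: main effects and interaction.

    Without ``repeated``, an ordinary factorial fit (statsmodels OLS, Type II
    sums of squares by default; override with ``ss_type``).  With
    ``repeated``, ``factor_b`` is treated as within-subject and ``factor_a``
    as between-group (univariate mixed-design partitioning, via pingouin);
    ``subject`` is then required.  A cell with no observations raises a
    design error.  Zero-variance designs (all observations identical)
    return F = 0, p = 1 for every effect.
    """
    for col in (dv, factor_a, factor_b):
        if col not in df.columns:
            raise InvalidSpecError(f"column {col!r} missing")
    counts = df.groupby([factor_a, factor_b], observed=True)[dv].count()
    la = df[factor_a].nunique()
    lb = df[factor_b].nunique()
    if la < 2 or lb < 2:
        raise InvalidSpecError("each factor needs >= 2 levels")
    if len(counts) < la * lb or (counts == 0).any():
        raise ConfigurationError("empty design cell")

    if repeated:
        if subject is None:
            raise ConfigurationError("repeated-measures ANOVA needs a subject column")
        import pingouin as pg
        aov = pg.mixed_anova(data=df, dv=dv, between=factor_a,
                             within=factor_b, subject=subject)
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        table = pd.DataFrame({
            "F": aov["F"].values, "p": aov[p_col].values,
            "df1": aov["DF1"].values, "df2": aov["DF2"].values,
        }, index=[factor_a, factor_b, f"{factor_a}:{factor_b}"])
        return AnovaResult(table=table, repeated=True, details={"pingouin": aov})

    data = df.rename(columns={dv: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=data).fit()
    aov = anova_lm(model, typ=ss_type)
    mapping = {"C(_a)": factor_a, "C(_b)": factor_b,
               "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    aov = aov.rename(index=mapping)
    table = pd.DataFrame({
        "F": aov["F"], "p": aov["PR(>F)"],
        "df": aov["df"], "sum_sq": aov["sum_sq"],
    }).drop(index="Residual")
    # all-constant data: 0/0 effects are "no effect" by convention
    resid_ss = float(aov.loc["Residual", "sum_sq"])
    tol = 1e-12 * max(float(np.sum(data["_y"]**2)), 1.0)
    if resid_ss < tol:
        zero = table["sum_sq"] < tol
        table.loc[zero, "F"] = 0.0
        table.loc[zero, "p"] = 1.0
    return AnovaResult(table=table, repeated=False, details={"anova_lm": aov})


# ------------------------------------------------------------- Holm-Sidak
@dataclass(frozen=True)
class HolmSidakResult:
    adjusted: np.ndarray         # in the input order
    reject: np.ndarray
    alpha: float


def holm_sidak(pvalues, alpha: float = 0.05) -> HolmSidakResult:
    """Step-down Holm-Sidak multiple-comparison adjustment.

    Sorted p_(i) (i = 1..m) is adjusted to 1 - (1 - p_(i))^(m - i + 1) with
    monotonicity enforced by a running maximum; decisions at ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return HolmSidakResult(adjusted=np.empty(0), reject=np.empty(0, bool),
                               alpha=alpha)
    if np.any((p < 0) | (p > 1)):
        raise InvalidSpecError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return HolmSidakResult(adjusted=adjusted, reject=adjusted < alpha,
                           alpha=alpha)
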