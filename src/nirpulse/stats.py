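"""Statistical battery for the windowed-median feature table.

Per feature: normality (Shapiro-Wilk, Kolmogorov-Smirnov against a fitted
normal) and variance-homogeneity (Bartlett) assumption checks; nonparametric
condition contrasts (two-sided Mann-Whitney U for the two-position tilting
contrast, Kruskal-Wallis across the Valsalva conditions); and a two-factor
linear model (condition x detector, with interaction) on the — conditionally
Box-Cox transformed — response, with Type II sums of squares since the
window counts per section are unbalanced by construction.

Observations are window-level feature medians treated as independent; no
subject-level random effect is fitted (documented limitation).  No multiple-
testing correction is applied across the nine features; a Bonferroni
significance column is reported alongside for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .features import FEATURE_NAMES

ALPHA = 0.05


@dataclass(frozen=True)
class StatTestResult:
    feature: str
    test: str
    statistic: float
    p_value: float
    alpha: float = ALPHA
    group: str = ""
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < self.alpha)


@dataclass
class BoxCoxFit:
    """Box-Cox power transform with an automatic positivity shift."""

    lambda_opt: float
    shift: float
    transformed: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float) + self.shift
        if np.any(x <= 0):
            raise ValueError("values not strictly positive after shift")
        if self.lambda_opt == 0:
            return np.log(x)
        return (x ** self.lambda_opt - 1.0) / self.lambda_opt


@dataclass
class FactorialModelResult:
    """F and p per model term, plus residual df and the transform used."""

    terms: dict[str, tuple[float, float]]
    residual_df: float
    boxcox_lambda: float | None = None
    factors: tuple[str, str] = ("condition", "detector")

    def p_value(self, term: str) -> float:
        return self.terms[term][1]


# ---------------------------------------------------------------------------
# assumption checks and nonparametric tests

def check_assumptions(
    values_by_group: dict[str, np.ndarray], feature: str = "", alpha: float = ALPHA
) -> list[StatTestResult]:
    """Shapiro-Wilk and KS-vs-fitted-normal per group, Bartlett across groups.

    Results are returned for inspection; nothing downstream is gated
    automatically.  A constant group yields NaN p-values with a warning note.
    """
    results: list[StatTestResult] = []
    arrays = {}
    for name, values in values_by_group.items():
        x = np.asarray(values, dtype=float)
        if len(x) < 3:
            raise ValueError(f"group {name!r} needs n >= 3")
        arrays[name] = x
        if np.ptp(x) == 0:
            for test in ("shapiro-wilk", "kolmogorov-smirnov"):
                results.append(
                    StatTestResult(feature, test, np.nan, np.nan, alpha, name,
                                   note="constant group; normality undefined")
                )
            continue
        w, p = sstats.shapiro(x)
        results.append(StatTestResult(feature, "shapiro-wilk", float(w), float(p), alpha, name))
        d, p = sstats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        results.append(
            StatTestResult(feature, "kolmogorov-smirnov", float(d), float(p), alpha, name)
        )
    if len(arrays) >= 2:
        if any(np.ptp(x) == 0 for x in arrays.values()):
            results.append(
                StatTestResult(feature, "bartlett", np.nan, np.nan, alpha,
                               note="constant group; variance test undefined")
            )
        else:
            stat, p = sstats.bartlett(*arrays.values())
            results.append(StatTestResult(feature, "bartlett", float(stat), float(p), alpha))
    return results


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, feature: str = "", alpha: float = ALPHA
) -> StatTestResult:
    """Two-sided Mann-Whitney U with tie correction.

    Exact enumeration is used for small no-tie samples (min(n) <= 8), the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and min(len(a), len(b)) <= 8) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatTestResult(
        feature, "mann-whitney-u", float(res.statistic), float(res.pvalue), alpha,
        note=method,
    )


def kruskal_wallis(
    groups: dict[str, np.ndarray], feature: str = "", alpha: float = ALPHA
) -> StatTestResult:
    """Kruskal-Wallis H with tie correction and chi-squared p-value."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(x) < 1 for x in arrays):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(x) for x in arrays) < 3:
        raise ValueError("need >= 3 observations in total")
    if np.ptp(np.concatenate(arrays)) == 0:
        return StatTestResult(feature, "kruskal-wallis", 0.0, 1.0, alpha,
                              note="all values identical")
    h, p = sstats.kruskal(*arrays)
    return StatTestResult(feature, "kruskal-wallis", float(h), float(p), alpha)


# ---------------------------------------------------------------------------
# Box-Cox and the factorial model

def boxcox_transform(values: np.ndarray) -> BoxCoxFit:
    """Maximum-likelihood Box-Cox transform after an automatic positivity shift.

    The shift is ``max(0, eps - min(values))`` with ``eps = 1e-6 * range``, so
    already-positive data are untouched.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError("Box-Cox needs n >= 10")
    rng_ = np.ptp(x)
    if rng_ == 0:
        raise ValueError("zero-range data cannot be Box-Cox transformed")
    shift = max(0.0, 1e-6 * rng_ - x.min())
    transformed, lam = sstats.boxcox(x + shift)
    return BoxCoxFit(lambda_opt=float(lam), shift=float(shift), transformed=transformed)


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("condition", "detector"),
    alpha: float = ALPHA,
    boxcox: str = "auto",
) -> FactorialModelResult:
    """Two-way linear model with interaction, Type II sums of squares.

    ``boxcox`` in {"auto", "always", "never"}: "auto" transforms the response
    only when any assumption check (normality per cell, Bartlett across
    cells) fails at ``alpha``, mirroring the conditional use of the transform
    in the analysis this reproduces.
    """
    if boxcox not in ("auto", "always", "never"):
        raise ValueError("boxcox must be 'auto', 'always' or 'never'")
    fa, fb = factors
    df = table[[response, fa, fb]].dropna().copy()
    levels_a = sorted(df[fa].unique())
    levels_b = sorted(df[fb].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby([fa, fb], observed=True).size()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValueError(f"empty cell ({fa}={la!r}, {fb}={lb!r})")

    y = df[response].to_numpy(dtype=float)
    lam: float | None = None
    transform = boxcox == "always"
    if boxcox == "auto":
        cells = {
            f"{la}|{lb}": df[(df[fa] == la) & (df[fb] == lb)][response].to_numpy()
            for la in levels_a
            for lb in levels_b
        }
        cells = {k: v for k, v in cells.items() if len(v) >= 3}
        if cells:
            checks = check_assumptions(cells, feature=response, alpha=alpha)
            transform = any(c.significant for c in checks)
    if transform:
        fit = boxcox_transform(y)
        y = fit.transformed
        lam = fit.lambda_opt

    model_df = pd.DataFrame({"y": y, "A": df[fa].to_numpy(), "B": df[fb].to_numpy()})
    model = smf.ols("y ~ C(A) * C(B)", data=model_df).fit()
    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    anova = sm.stats.anova_lm(model, typ=2)

    name_map = {"C(A)": fa, "C(B)": fb, "C(A):C(B)": f"{fa}:{fb}"}
    terms = {
        name_map[row_name]: (float(row["F"]), float(row["PR(>F)"]))
        for row_name, row in anova.iterrows()
        if row_name in name_map
    }
    return FactorialModelResult(
        terms=terms, residual_df=float(model.df_resid), boxcox_lambda=lam, factors=factors
    )


# ---------------------------------------------------------------------------
# battery over the feature table

def feature_statistics(
    table: pd.DataFrame,
    intervention: str,
    alpha: float = ALPHA,
    boxcox: str = "auto",
    pool_supine: bool = True,
) -> pd.DataFrame:
    """Run the per-feature battery over one intervention's feature table.

    For tilting, the nonparametric contrast is supine (supine1 + supine2
    pooled by default) versus Trendelenburg per detector (Mann-Whitney U);
    for Valsalva, Kruskal-Wallis across baseline and the three maneuvers per
    detector.  The factorial model uses condition x detector with
    interaction.  Returns a tidy results table with Bonferroni flags at 9
    features.
    """
    df = table[table["intervention"] == intervention].copy()
    if df.empty:
        raise ValueError(f"no rows for intervention {intervention!r}")
    if intervention == "tilting":
        if pool_supine:
            df["condition"] = df["condition"].replace({"supine1": "supine", "supine2": "supine"})
        else:
            df = df[df["condition"].isin(["supine1", "trendelenburg"])]
            df["condition"] = df["condition"].replace({"supine1": "supine"})

    rows = []
    for feat in FEATURE_NAMES:
        for det in ("distal", "proximal"):
            sub = df[df["detector"] == det]
            groups = {
                str(c): g[feat].to_numpy() for c, g in sub.groupby("condition", observed=True)
            }
            if intervention == "tilting":
                res = mann_whitney_u(
                    groups.get("supine", np.array([])),
                    groups.get("trendelenburg", np.array([])),
                    feature=feat, alpha=alpha,
                )
            else:
                res = kruskal_wallis(groups, feature=feat, alpha=alpha)
            rows.append(
                {
                    "feature": feat, "contrast": f"condition[{det}]", "test": res.test,
                    "statistic": res.statistic, "p_value": res.p_value,
                }
            )
        model = factorial_anova(df, feat, alpha=alpha, boxcox=boxcox)
        for term, (fstat, p) in model.terms.items():
            rows.append(
                {
                    "feature": feat, "contrast": term, "test": "factorial-anova",
                    "statistic": fstat, "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < alpha
    out["significant_bonferroni"] = out["p_value"] < alpha / len(FEATURE_NAMES)
    return out
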