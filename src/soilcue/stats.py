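"""Factorial and pairwise group comparisons, and correlation screening.

The study design crosses mycorrhizal type (AM vs ECM) with sampling position
(rhizosphere vs non-rhizosphere), unbalanced at the species level (8 AM vs 7
ECM species). Responses whose residuals look Gaussian (Shapiro–Wilk, after a
log-transform attempt) are analysed with a two-way type-II ANOVA; the rest
with the Scheirer–Ray–Hare extension of Kruskal–Wallis, which runs the same
factorial decomposition on mid-ranks and refers each effect's
SS / (SS_total/(N−1)) to a χ² distribution. Pairwise contrasts use Wilcoxon
tests (rank-sum unpaired by default; signed-rank when samples are paired by
tree individual), and predictor screening uses Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

FACTOR_M_LEVELS = ("AM", "ECM")
FACTOR_P_LEVELS = ("non_rhizosphere", "rhizosphere")

_EFFECT_LABELS = {
    "C(factor_m)": "mycorrhizal_type",
    "C(factor_p)": "position",
    "C(factor_m):C(factor_p)": "interaction",
}


def _check_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    required = {"response", "factor_m", "factor_p"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    data = dataset.dropna(subset=["response"]).copy()
    cells = data.groupby(["factor_m", "factor_p"], observed=True).size()
    if (cells < 2).any() or len(cells) < 2:
        raise ValueError("need >= 2 observations in >= 2 design cells")
    return data


def _formula(data: pd.DataFrame, response_col: str) -> str:
    """Full factorial formula, dropping any factor observed at a single level.

    Dropping single-level factors lets the factorial tests collapse cleanly
    to their one-way counterparts (ANOVA F, Kruskal–Wallis H).
    """
    terms = [f"C({f})" for f in ("factor_m", "factor_p") if data[f].nunique() > 1]
    if not terms:
        raise ValueError("no factor varies")
    return f"{response_col} ~ {' * '.join(terms)}"


def _type2_anova_table(data: pd.DataFrame, response_col: str = "response") -> pd.DataFrame:
    model = smf.ols(_formula(data, response_col), data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def two_way_anova(dataset: pd.DataFrame) -> pd.DataFrame:
    """Two-way type-II ANOVA of response ~ mycorrhizal type × position.

    Type-II sums of squares accommodate the unbalanced design (each main
    effect adjusted for the other, the interaction for both). Returns a tidy
    frame with one row per effect: effect, df, sum_sq, F, p, method.
    """
    data = _check_dataset(dataset)
    table = _type2_anova_table(data)
    rows = [
        {
            "effect": _EFFECT_LABELS.get(name, name),
            "df": float(table.loc[name, "df"]),
            "sum_sq": float(table.loc[name, "sum_sq"]),
            "statistic": float(table.loc[name, "F"]),
            "p": float(table.loc[name, "PR(>F)"]),
            "method": "two_way_anova_type2",
        }
        for name in table.index
        if name != "Residual"
    ]
    return pd.DataFrame(rows)


def scheirer_ray_hare(dataset: pd.DataFrame) -> pd.DataFrame:
    """Scheirer–Ray–Hare test: the two-way factorial analysis on mid-ranks.

    Values are replaced by mid-ranks over the whole dataset; effect sums of
    squares are the type-II decomposition on the ranks; each effect's
    H = SS_effect / (SS_total / (N−1)) is referred to χ² with the effect's
    df. Computing the denominator from the variance of the *mid-ranks
    actually assigned* builds the tie correction in: without ties it equals
    N(N+1)/12, with ties it shrinks by exactly the classical factor
    1 − Σ(t³−t)/(N³−N). With a single factor this reduces exactly to the
    (tie-corrected) Kruskal–Wallis H test.
    """
    data = _check_dataset(dataset)
    ranks = sps.rankdata(data["response"].to_numpy())
    data = data.assign(_rank=ranks)
    n = len(ranks)
    ss_total = float(((ranks - ranks.mean()) ** 2).sum())
    ms_total = ss_total / (n - 1)
    rows = []
    if ms_total == 0:  # all values tied
        for label in _EFFECT_LABELS.values():
            rows.append(
                {"effect": label, "df": float("nan"), "sum_sq": 0.0,
                 "statistic": 0.0, "p": 1.0, "method": "scheirer_ray_hare"}
            )
        return pd.DataFrame(rows)
    table = _type2_anova_table(data, response_col="_rank")
    for name in table.index:
        if name == "Residual":
            continue
        df_eff = float(table.loc[name, "df"])
        h = float(table.loc[name, "sum_sq"]) / ms_total
        rows.append(
            {
                "effect": _EFFECT_LABELS.get(name, name),
                "df": df_eff,
                "sum_sq": float(table.loc[name, "sum_sq"]),
                "statistic": h,
                "p": float(sps.chi2.sf(h, df_eff)),
                "method": "scheirer_ray_hare",
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_pair(
    group_a: np.ndarray,
    group_b: np.ndarray,
    paired: bool = False,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon comparison of two groups: (statistic, p).

    Unpaired: Mann–Whitney rank-sum U, exact for n ≤ 25 per group (no ties),
    otherwise normal approximation with continuity correction. Paired:
    Wilcoxon signed-rank on within-pair differences.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        if np.all(a == b):
            raise ValueError("all paired differences are tied at zero")
        res = sps.wilcoxon(a, b, alternative=alternative)
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (max(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_screen(predictors: pd.DataFrame, responses: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of every predictor × response column pair.

    Inputs are aligned on index (sample id); rows with a missing value in
    either member of a pair are dropped pairwise. Constant columns give NaN
    with a reason flag. Returns a tidy frame: predictor, response, n, rho, p,
    reason. Two-sided p-values via the t approximation. No multiple-testing
    correction is applied by default (set ``reason`` aside and correct
    downstream if desired).
    """
    predictors, responses = predictors.align(responses, join="inner", axis=0)
    rows = []
    for pname, pcol in predictors.items():
        for rname, rcol in responses.items():
            mask = pcol.notna() & rcol.notna()
            x, y = pcol[mask].to_numpy(), rcol[mask].to_numpy()
            reason = ""
            if mask.sum() < 4:
                rho, p, reason = float("nan"), float("nan"), "too_few_observations"
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p, reason = float("nan"), float("nan"), "constant_column"
            else:
                rho, p = sps.spearmanr(x, y)
            rows.append(
                {
                    "predictor": pname,
                    "response": rname,
                    "n": int(mask.sum()),
                    "rho": float(rho),
                    "p": float(p),
                    "reason": reason,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RouteDecision:
    """Outcome of the normality gate for one response."""

    route: str  # 'parametric' | 'nonparametric'
    shapiro_p_raw: float
    shapiro_p_log: float | None
    log_transformed: bool

    def describe(self) -> str:
        base = f"route={self.route} shapiro_p_raw={self.shapiro_p_raw:.4g}"
        if self.shapiro_p_log is not None:
            base += f" shapiro_p_log={self.shapiro_p_log:.4g} log={self.log_transformed}"
        return base


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> RouteDecision:
    """Choose parametric vs nonparametric analysis from a Shapiro–Wilk test.

    If normality of ``values`` (typically model residuals) is not rejected at
    ``alpha``, route to the two-way ANOVA. Otherwise, when all values are
    positive, a natural-log transform is attempted and re-tested; failing
    that, route to Scheirer–Ray–Hare. The full decision trail is returned.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise ValueError("need n >= 3")
    p_raw = float(sps.shapiro(v).pvalue) if np.ptp(v) > 0 else 0.0
    if p_raw >= alpha:
        return RouteDecision("parametric", p_raw, None, False)
    if (v > 0).all():
        p_log = float(sps.shapiro(np.log(v)).pvalue) if np.ptp(v) > 0 else 0.0
        if p_log >= alpha:
            return RouteDecision("parametric", p_raw, p_log, True)
        return RouteDecision("nonparametric", p_raw, p_log, False)
    return RouteDecision("nonparametric", p_raw, None, False)


def factorial_test(dataset: pd.DataFrame) -> pd.DataFrame:
    """Gate on residual normality, then run the routed factorial test.

    Residuals are taken from the full two-way OLS fit; the Shapiro–Wilk gate
    (with log-transform attempt on the response) decides between the type-II
    ANOVA and Scheirer–Ray–Hare. The route and decision trail are recorded in
    the ``route`` column of the returned tidy frame.
    """
    data = _check_dataset(dataset)

    def resid_shapiro(frame: pd.DataFrame) -> float:
        model = smf.ols("response ~ C(factor_m) * C(factor_p)", data=frame).fit()
        resid = model.resid.to_numpy()
        return float(sps.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 0.0

    p_raw = resid_shapiro(data)
    if p_raw >= 0.05:
        result = two_way_anova(data)
        result["route"] = f"parametric shapiro_p_resid={p_raw:.4g}"
        return result
    if (data["response"] > 0).all():
        logged = data.assign(response=np.log(data["response"]))
        p_log = resid_shapiro(logged)
        if p_log >= 0.05:
            result = two_way_anova(logged)
            result["route"] = (
                f"parametric(log response) shapiro_p_resid={p_raw:.4g} "
                f"shapiro_p_resid_log={p_log:.4g}"
            )
            return result
    result = scheirer_ray_hare(data)
    result["route"] = f"nonparametric shapiro_p_resid={p_raw:.4g}"
    return result
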