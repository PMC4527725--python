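"""The cohort statistics pipeline: routing, time courses, group contrasts, mortality.

Test choice mirrors the experiment's analysis plan: distributions are routed
by a one-sample Kolmogorov–Smirnov test against a normal with the sample's
own mean/SD (parametric iff p ≥ α); within-group time courses use
repeated-measures ANOVA (parametric) or the Friedman test, with vs-baseline
post-hoc contrasts; survivor vs non-survivor contrasts at a time point use
the unpaired t test or Mann–Whitney U; mortality is modeled by multivariable
logistic regression, by default with Firth's bias-reduced likelihood so the
fit stays finite under separation at n = 20.

No adjustment is made for multiple testing *across variables* (only the
post-hoc contrasts within one omnibus test are adjusted) — deliberately, to
mirror common practice in this literature.  Interpret marginal p-values
accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .series import TIMEPOINT_LABELS

__all__ = [
    "Route",
    "ComparisonResult",
    "MortalityModel",
    "normality_route",
    "within_group_timecourse",
    "between_group_compare",
    "mortality_model",
    "summary_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class Route:
    route: str  # "parametric" | "nonparametric"
    p_value: float

    @property
    def parametric(self) -> bool:
        return self.route == "parametric"


def normality_route(samples, alpha: float = ALPHA) -> Route:
    """Route a sample to parametric or nonparametric analysis.

    One-sample KS against Normal(mean, sd) with parameters estimated from the
    sample (no small-sample correction — conservative toward the parametric
    branch).  Constant samples are nonparametric with a warning.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations to assess normality")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        warnings.warn("constant sample: normality undefined, routing nonparametric")
        return Route("nonparametric", 0.0)
    stat = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return Route("parametric" if stat.pvalue >= alpha else "nonparametric", stat.pvalue)


@dataclass
class ComparisonResult:
    """One statistical contrast, within-group over time or between groups."""

    variable: str
    scope: str  # "within_group" | "between_group"
    groups: tuple[str, ...]
    timepoints: tuple[str, ...]
    test_used: str | None  # rm_anova | friedman | t_unpaired | mann_whitney
    statistic: float | None
    p_value: float | None
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    significant: bool | None = None
    alpha: float = ALPHA
    skipped: bool = False
    reason: str | None = None


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def _complete_case_pivot(cohort: pd.DataFrame, variable: str, group: str) -> pd.DataFrame:
    sub = cohort[(cohort["variable"] == variable) & (cohort["group"] == group)]
    wide = sub.pivot_table(index="animal_id", columns="timepoint", values="value",
                           observed=True)
    wide = wide.dropna(axis=1, how="all")  # the group's available time points
    wide = wide.dropna(axis=0, how="any")  # complete cases over those
    order = [tp for tp in TIMEPOINT_LABELS if tp in wide.columns]
    return wide[order]


def within_group_timecourse(
    cohort: pd.DataFrame,
    variable: str,
    group: str,
    alpha: float = ALPHA,
    baseline: str = "Baseline",
) -> ComparisonResult:
    """Omnibus time-course test for one group, with vs-baseline post-hoc contrasts.

    Complete-case over the group's available time points (non-survivors
    contribute only Baseline…Shock60).  Routing uses the pooled within-cell
    residuals; post-hoc contrasts are paired t (parametric) or Wilcoxon
    signed-rank (nonparametric) vs baseline, Holm-adjusted.
    """
    wide = _complete_case_pivot(cohort, variable, group)
    tps = list(wide.columns)
    if len(tps) < 2:
        raise ValueError("need at least 2 time points")
    if len(wide) < 3:
        raise ValueError("need at least 3 animals with complete data")
    if baseline not in tps:
        raise ValueError(f"baseline time point {baseline!r} not present")

    values = wide.to_numpy()
    resid = values - values.mean(axis=0, keepdims=True)
    if np.allclose(values, values[:, [0]]):
        # zero within-animal variation: the omnibus F/chi2 is 0/0; no effect
        return ComparisonResult(variable, "within_group", (group,), tuple(tps),
                                "rm_anova", 0.0, 1.0, [], False, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        route = normality_route(resid.ravel(), alpha)

    if route.parametric:
        from statsmodels.stats.anova import AnovaRM

        long = wide.reset_index().melt(id_vars="animal_id", var_name="timepoint",
                                       value_name="value")
        fit = AnovaRM(long, depvar="value", subject="animal_id",
                      within=["timepoint"]).fit()
        stat = float(fit.anova_table["F Value"].iloc[0])
        p = float(fit.anova_table["Pr > F"].iloc[0])
        test = "rm_anova"
    else:
        stat, p = sps.friedmanchisquare(*[values[:, j] for j in range(len(tps))])
        stat, p = float(stat), float(p)
        test = "friedman"

    posthoc: list[tuple[tuple[str, str], float]] = []
    base = wide[baseline].to_numpy()
    raw = []
    pairs = []
    for tp in tps:
        if tp == baseline:
            continue
        other = wide[tp].to_numpy()
        if route.parametric:
            pr = sps.ttest_rel(other, base).pvalue
        else:
            diff = other - base
            pr = 1.0 if np.all(diff == 0) else sps.wilcoxon(other, base).pvalue
        raw.append(float(pr))
        pairs.append((baseline, tp))
    for pair, padj in zip(pairs, _holm(raw)):
        posthoc.append((pair, padj))
    return ComparisonResult(variable, "within_group", (group,), tuple(tps),
                            test, stat, p, posthoc, p < alpha, alpha)


def between_group_compare(
    cohort: pd.DataFrame, variable: str, timepoint: str, alpha: float = ALPHA
) -> ComparisonResult:
    """Survivor vs non-survivor contrast at one time point.

    Unpaired t when both groups route parametric, else Mann–Whitney U
    (two-sided).  When a group has no data at the time point (non-survivors
    post-resuscitation) the comparison is skipped with an explicit reason.
    """
    if timepoint not in TIMEPOINT_LABELS:
        raise ValueError(f"unknown time point {timepoint!r}")
    sub = cohort[(cohort["variable"] == variable) & (cohort["timepoint"] == timepoint)]
    samples = {g: sub.loc[sub["group"] == g, "value"].to_numpy() for g in ("S", "NS")}
    for g, x in samples.items():
        if len(x) < 2:
            return ComparisonResult(
                variable, "between_group", ("S", "NS"), (timepoint,),
                None, None, None, [], None, alpha, skipped=True,
                reason=f"group {g} has {len(x)} value(s) for {variable} at "
                       f"{timepoint} (fewer than 2); comparison not possible",
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parametric = all(normality_route(x, alpha).parametric for x in samples.values())
    if parametric:
        res = sps.ttest_ind(samples["S"], samples["NS"], equal_var=True)
        test = "t_unpaired"
    else:
        res = sps.mannwhitneyu(samples["S"], samples["NS"], alternative="two-sided")
        test = "mann_whitney"
    stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(variable, "between_group", ("S", "NS"), (timepoint,),
                            test, stat, p, [], p < alpha, alpha)


# ---------------------------------------------------------------------------
# mortality model
# ---------------------------------------------------------------------------


def _firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    fixed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
):
    """Firth's bias-reduced logistic regression (modified-score IRLS).

    The score is penalized by Jeffreys' prior, which keeps estimates finite
    under complete separation.  With ``fixed`` set, that coefficient is
    constrained to zero while the penalty keeps using the full design — the
    profile fit needed for penalized likelihood-ratio tests.
    Returns (beta, se, converged).
    """
    n, p = X.shape
    free = [j for j in range(p) if j != fixed]
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        info_inv = np.linalg.pinv(info)
        sq = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", sq, info_inv, sq)
        score = X.T @ (y - mu + h * (0.5 - mu))
        delta = np.linalg.solve(info[np.ix_(free, free)], score[free])
        # step-halving for stability
        step = 1.0
        while np.max(np.abs(step * delta)) > 5.0:
            step *= 0.5
        beta[free] += step * delta
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se, converged


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Log-likelihood plus the Jeffreys penalty 0.5·log|I(beta)|."""
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    w = mu * (1.0 - mu)
    _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return ll + 0.5 * logdet


def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    """In-sample discrimination (area under the ROC curve) via the rank statistic."""
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


@dataclass
class MortalityModel:
    """A multivariable logistic model of mortality (outcome 1 = non-survivor)."""

    timepoint: str
    predictors: list[str]
    params: pd.DataFrame  # coef, se, z, p, p_adj per term (standardized scale;
    # p is a penalized LRT p for predictors under the firth method)
    selected_predictors: list[str]
    dropped: list[str]
    method: str  # "firth" | "ml"
    converged: bool
    n: int
    auc: float
    alpha: float = ALPHA


def mortality_model(
    cohort: pd.DataFrame,
    predictors: list[str],
    timepoint: str,
    penalized: bool = True,
    alpha: float = ALPHA,
) -> MortalityModel:
    """Fit the multivariable mortality model at one time point.

    Predictors are z-standardized; zero-variance predictors are dropped with
    a warning.  A predictor is *selected* iff its Holm-adjusted p < α, using
    penalized likelihood-ratio tests under the default Firth fit (calibrated
    near the nominal level at n = 20, where the Firth Wald test is not) and
    Wald tests under the plain ML fit; an empty selection is a valid outcome.
    """
    if timepoint not in TIMEPOINT_LABELS:
        raise ValueError(f"unknown time point {timepoint!r}")
    sub = cohort[(cohort["timepoint"] == timepoint)
                 & (cohort["variable"].isin(predictors))]
    wide = sub.pivot_table(index="animal_id", columns="variable", values="value",
                           observed=True)
    groups = cohort[["animal_id", "group"]].drop_duplicates().set_index("animal_id")
    wide = wide.join(groups).dropna()
    y = (wide["group"] == "NS").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has fewer than 2 classes at this time point")

    kept, dropped = [], []
    for v in predictors:
        if v not in wide.columns:
            raise ValueError(f"predictor {v!r} not measured at {timepoint}")
        if np.std(wide[v].to_numpy()) == 0:
            warnings.warn(f"zero-variance predictor {v!r} dropped")
            dropped.append(v)
        else:
            kept.append(v)
    if not kept:
        raise ValueError("no usable predictors after dropping zero-variance terms")

    Xraw = wide[kept].to_numpy(dtype=float)
    Xstd = (Xraw - Xraw.mean(axis=0)) / Xraw.std(axis=0, ddof=1)
    X = np.column_stack([np.ones(len(Xstd)), Xstd])

    if penalized:
        beta, se, converged = _firth_logistic(X, y)
        # per-predictor penalized likelihood-ratio tests: the Wald test is
        # severely conservative under the Firth penalty at this sample size
        ll_full = _penalized_loglik(X, y, beta)
        p_terms = []
        for j in range(1, X.shape[1]):
            beta0, _, _ = _firth_logistic(X, y, fixed=j)
            stat = 2.0 * (ll_full - _penalized_loglik(X, y, beta0))
            p_terms.append(float(sps.chi2.sf(max(stat, 0.0), 1)))
        method = "firth"
    else:
        import statsmodels.api as sm

        fit = sm.Logit(y, X).fit(disp=False)
        beta, se, converged = fit.params, fit.bse, fit.mle_retvals["converged"]
        p_terms = list(fit.pvalues[1:])
        method = "ml"

    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = np.array([2.0 * sps.norm.sf(abs(z[0]))] + p_terms)
    p_adj = np.array([np.nan] + _holm(p_terms))
    params = pd.DataFrame(
        {"coef": beta, "se": se, "z": z, "p": p, "p_adj": p_adj},
        index=["intercept"] + kept,
    )
    selected = [v for v, pa in zip(kept, p_adj[1:]) if pa < alpha]
    auc = _auc(X @ beta, y)
    return MortalityModel(timepoint, kept, params, selected, dropped, method,
                          converged, len(y), auc, alpha)


def summary_table(
    cohort: pd.DataFrame, variables: list[str] | None = None, alpha: float = ALPHA
) -> pd.DataFrame:
    """Summary cells per variable × group × time point (the Table-1 shape).

    Mean ± SD always; median and IQR added where the cell routes
    nonparametric.  Cells a group never measured (non-survivors after
    Shock60) are simply absent.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    df = cohort
    if variables is not None:
        df = df[df["variable"].isin(variables)]
    rows = []
    for (var, grp, tp), cell in df.groupby(["variable", "group", "timepoint"],
                                           observed=True):
        x = cell["value"].to_numpy()
        n = len(x)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if n > 1 else float("nan")
        if n >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                route = normality_route(x, alpha).route
        else:
            route = "parametric"
        q1, med, q3 = (np.percentile(x, q) for q in (25, 50, 75))
        rows.append({
            "variable": var, "group": grp, "timepoint": tp, "n": n,
            "mean": mean, "sd": sd, "median": float(med),
            "iqr_lo": float(q1), "iqr_hi": float(q3), "route": route,
        })
    out = pd.DataFrame(rows)
    out["timepoint"] = pd.Categorical(out["timepoint"], categories=TIMEPOINT_LABELS,
                                      ordered=True)
    return out.sort_values(["variable", "group", "timepoint"]).reset_index(drop=True)
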