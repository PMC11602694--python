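"""Phenotype descriptors, PCA fitness scoring and response modelling.

Turns daily necrosis trajectories from repeated common-garden heat-stress
assays into:

* per-population daily descriptors (mean extent of injury, % affected,
  % dead) and categorical impact classes,
* a PCA-based individual fitness proxy (PC1 scores over the late assay
  days, where necrosis development carries the signal),
* Box–Cox-transformed response models — fixed population × year effects
  with and without a per-colony random intercept — compared by AIC and
  likelihood-ratio test, with Tukey-style year contrasts,
* a likelihood-based variance partition over the design factors,
* per-colony random intercepts ("nec-int"), the individual fitness proxy
  used downstream in the heterosis test,
* a one-way ANOVA + Tukey HSD for in-situ survey necrosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: impact-class bin edges on % necrosis: none <10, low 10–30,
#: moderate >30–60, severe >60
IMPACT_CLASSES = ("none", "low", "moderate", "severe")

_PANEL_COLUMNS = ["colony_id", "population", "year", "day", "necrosis_pct"]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check necrosis-panel schema and invariants; return a sorted copy.

    Values must sit on the 5% grid in [0, 100] and be non-decreasing in
    day within each colony-year.
    """
    missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns {missing}")
    if panel.empty:
        raise ValueError("panel is empty")
    vals = panel["necrosis_pct"].to_numpy(float)
    if ((vals < 0) | (vals > 100)).any() or (np.mod(vals, 5) != 0).any():
        raise ValueError("necrosis_pct must lie on the 5% grid in [0, 100]")
    out = panel.sort_values(["colony_id", "year", "day"]).reset_index(drop=True)
    dec = out.groupby(["colony_id", "year"])["necrosis_pct"].diff() < 0
    if dec.any():
        bad = out.loc[dec, ["colony_id", "year"]].iloc[0]
        raise ValueError(
            f"necrosis decreases within colony-year {bad.colony_id}/{bad.year}"
        )
    return out


def apply_inclusion_rule(panel: pd.DataFrame, min_years: int = 2) -> pd.DataFrame:
    """Keep colonies assayed in at least ``min_years`` distinct years."""
    counts = panel.groupby("colony_id")["year"].nunique()
    keep = counts.index[counts >= min_years]
    return panel[panel["colony_id"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Descriptors and impact classes
# ---------------------------------------------------------------------------

def compute_daily_descriptors(panel: pd.DataFrame) -> pd.DataFrame:
    """Daily summary per (population, year, day).

    Returns mean extent of injury with its standard error, the
    percentage of affected colonies (> 10% necrosis) and the percentage
    of dead colonies (100% necrosis).  Empty groups are simply absent.
    """
    panel = validate_panel(panel)

    def _agg(g: pd.Series) -> pd.Series:
        v = g.to_numpy(float)
        return pd.Series({
            "n": len(v),
            "mean_extent": v.mean(),
            "se_extent": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            "pct_affected": 100.0 * (v > 10).mean(),
            "pct_dead": 100.0 * (v == 100).mean(),
        })

    out = (panel.groupby(["population", "year", "day"])["necrosis_pct"]
           .apply(_agg).unstack().reset_index())
    out["n"] = out["n"].astype(int)
    return out


def classify_impact(necrosis_pct: float) -> str:
    """Impact class of a % necrosis value.

    none < 10, low 10–30, moderate > 30–60, severe > 60 (boundaries at
    10 and 30 belong to "low", 60 to "moderate").
    """
    x = float(necrosis_pct)
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"necrosis percentage out of range: {x}")
    if x < 10.0:
        return "none"
    if x <= 30.0:
        return "low"
    if x <= 60.0:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# PCA fitness proxy
# ---------------------------------------------------------------------------

@dataclass
class FitnessScores:
    """PC1 fitness scores per colony-year case plus PCA metadata."""

    scores: pd.DataFrame          # colony_id, population, year, pc1_score
    variance_explained: np.ndarray    # per component, definitive PCA (%)
    exploratory_variance_explained: np.ndarray  # per component, all-day PCA (%)
    loadings: pd.Series           # day -> PC1 loading (definitive PCA)
    trim_before_day: int
    dropped_cases: list = field(default_factory=list)
    constant_days: list = field(default_factory=list)


def _standardized_pca(mat: np.ndarray):
    """PCA of the column-standardized matrix (population-SD scaling).

    Returns (scores, pct_variance_per_component, loadings of PC1).
    """
    centred = mat - mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    z = centred / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = s ** 2 / z.shape[0]
    pct = 100.0 * eig / eig.sum()
    scores = u * s  # case coordinates
    return scores, pct, vt


def fit_fitness_pca(panel: pd.DataFrame, trim_before_day: int = 10) -> FitnessScores:
    """PCA fitness proxy: PC1 score per colony-year case.

    Cases are colony × year rows, variables are daily % necrosis
    columns.  An exploratory PCA over all days is reported; the
    definitive PCA uses days >= ``trim_before_day``, where necrosis
    development discriminates cases.  Columns are standardized
    (correlation PCA); constant columns carry no signal and are dropped.
    Cases missing any retained day are dropped with a warning.  PC1 is
    oriented to correlate positively with final-day necrosis.
    """
    panel = validate_panel(panel)
    wide = panel.pivot_table(index=["colony_id", "population", "year"],
                             columns="day", values="necrosis_pct")
    complete = wide.dropna()
    dropped = sorted(set(map(tuple, wide.index)) - set(map(tuple, complete.index)))
    if dropped:
        warnings.warn(f"dropping {len(dropped)} cases with missing days")
    if len(complete) < 3:
        raise ValueError("need >= 3 complete cases for the PCA")

    def _run(cols: list) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
        sub = complete[cols]
        keep = [c for c in cols if sub[c].nunique() > 1]
        if len(keep) < 2:
            raise ValueError("need >= 2 non-constant day columns for the PCA")
        scores, pct, vt = _standardized_pca(sub[keep].to_numpy(float))
        return scores, pct, vt, keep

    all_days = list(complete.columns)
    _, pct_all, _, _ = _run(all_days)
    late_days = [d for d in all_days if d >= trim_before_day]
    scores, pct, vt, kept = _run(late_days)

    pc1 = scores[:, 0]
    final_day = complete[max(kept)].to_numpy(float)
    sign = 1.0
    r = np.corrcoef(pc1, final_day)[0, 1] if final_day.std() > 0 else 1.0
    if r < 0:
        sign = -1.0
    pc1 = sign * pc1
    loadings = pd.Series(sign * vt[0], index=kept, name="pc1_loading")

    out = complete.index.to_frame(index=False)
    out["pc1_score"] = pc1
    return FitnessScores(
        scores=out,
        variance_explained=pct,
        exploratory_variance_explained=pct_all,
        loadings=loadings,
        trim_before_day=trim_before_day,
        dropped_cases=dropped,
        constant_days=[d for d in late_days if d not in kept],
    )


# ---------------------------------------------------------------------------
# Box–Cox transform
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxResult:
    scores: pd.DataFrame      # input frame + 'transformed' column
    lmbda: float
    shift: float
    shapiro_p: float
    levene_p: float


def _boxcox(x: np.ndarray, lmbda: float) -> np.ndarray:
    if abs(lmbda) < 1e-12:
        return np.log(x)
    return (x ** lmbda - 1.0) / lmbda


def boxcox_transform(scores: pd.DataFrame, score_col: str = "pc1_score") -> BoxCoxResult:
    """Box–Cox transform of the fitness scores.

    Scores are shifted to strict positivity where needed (shift =
    1 − min for non-positive scores, 0 otherwise) and λ is
    chosen by profile maximum likelihood under the fixed-effect
    population × year model, the residual structure the transform is
    meant to normalise.  Shapiro–Wilk (residual normality) and Levene
    (homoscedasticity across years) p-values are reported.
    """
    x = scores[score_col].to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    if x.std() == 0:
        raise ValueError("constant scores cannot be transformed")
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    pos = x + shift
    df = scores.copy()
    n = len(pos)
    log_jac = np.log(pos).sum()

    def _neg_profile_ll(lmbda: float) -> float:
        df["_y"] = _boxcox(pos, lmbda)
        fit = ols("_y ~ C(population) * C(year)", data=df).fit()
        rss = float(fit.ssr)
        return 0.5 * n * np.log(rss / n) - (lmbda - 1.0) * log_jac

    res = optimize.minimize_scalar(_neg_profile_ll, bounds=(-3.0, 3.0),
                                   method="bounded")
    lmbda = float(res.x)
    df["transformed"] = _boxcox(pos, lmbda)
    fit = ols("transformed ~ C(population) * C(year)", data=df).fit()
    shapiro_p = float(stats.shapiro(fit.resid).pvalue)
    groups = [g.to_numpy() for _, g in df.groupby("year")["transformed"]]
    levene_p = float(stats.levene(*groups).pvalue)
    df = df.drop(columns="_y", errors="ignore")
    return BoxCoxResult(df, lmbda, shift, shapiro_p, levene_p)


# ---------------------------------------------------------------------------
# Response models, random intercepts, variance partition
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    models: pd.DataFrame          # name, loglik, df, aic
    lrt_chi2: float               # model 2 vs model 1 (random intercept)
    lrt_df: int
    lrt_p: float
    fixed_factor_tests: pd.DataFrame  # factor, chi2, df, p (drop from model 2)
    tukey_year: pd.DataFrame      # pairwise year contrasts
    boxcox_lambda: float
    preferred: str
    singular: bool
    sigma_u: float = np.nan       # random-intercept SD (model 2, ML)
    sigma_resid: float = np.nan   # residual SD (model 2, ML)


@dataclass
class VariancePartition:
    contributions: pd.DataFrame   # factor, delta_loglik, delta_df, raw, contribution_pct
    loglik_full: float


def _fit_fixed(df: pd.DataFrame, formula: str):
    return ols(formula, data=df).fit()


def _fit_mixed(df: pd.DataFrame, fixed_formula: str):
    """Mixed model with per-colony random intercept, fitted by ML.

    The profiled likelihood in the variance component is not always easy
    for a single optimizer (local optima, and a boundary at zero
    variance), so several optimizers are tried and the best-likelihood
    fit is kept.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mixedlm(fixed_formula, data=df, groups=df["colony_id"])
        best = None
        last = None
        for method in (["lbfgs", "bfgs", "cg"], "powell", "nm"):
            try:
                fit = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError as exc:
                last = exc
                continue
            if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
                best = fit
    if best is None:
        raise np.linalg.LinAlgError(
            f"mixed fit failed for '{fixed_formula}': {last}")
    return best


def _mixed_loglik(df: pd.DataFrame, fixed_formula: str) -> tuple[float, int]:
    """ML log-likelihood and df of the random-intercept model.

    The ML optimum can sit at the zero-variance boundary, where the
    likelihood equals the fixed-effect model's; the boundary value is a
    feasible point, so the reported log-likelihood is never below it
    (this also rescues optimizer failures on degenerate fits).  The
    parameter count always includes the variance component.
    """
    ll_ols, df_fixed = _loglik_df(_fit_fixed(df, fixed_formula), mixed=False)
    try:
        fit = _fit_mixed(df, fixed_formula)
        ll, df_mixed = _loglik_df(fit, mixed=True)
    except np.linalg.LinAlgError:
        return ll_ols, df_fixed + 1
    return max(ll, ll_ols), df_mixed


def _loglik_df(fit, mixed: bool) -> tuple[float, int]:
    k_fixed = len(fit.fe_params) if mixed else len(fit.params)
    # variance parameters: residual, plus random-intercept variance if mixed
    return float(fit.llf), k_fixed + (2 if mixed else 1)


def fit_response_models(scores: pd.DataFrame,
                        response: str = "transformed") -> tuple[ModelComparison, pd.Series]:
    """Fit and compare the two response models.

    Model 1: fixed population, year and their interaction.  Model 2:
    model 1 plus a per-colony random intercept (a colony-specific
    baseline of resistance).  Both are fitted by maximum likelihood so
    log-likelihoods and AIC are comparable.  Returns the comparison and
    the per-colony random intercepts ("nec-int") from model 2.
    """
    for col, nmin in (("population", 2), ("year", 2)):
        if scores[col].nunique() < nmin:
            raise ValueError(f"need >= {nmin} levels of {col}")
    obs_per_colony = scores.groupby("colony_id")["year"].nunique()
    if (obs_per_colony < 2).any():
        raise ValueError("every colony must be observed in >= 2 years; "
                         "apply the inclusion rule first")

    formula = f"{response} ~ C(population) * C(year)"
    m1 = _fit_fixed(scores, formula)
    m2 = _fit_mixed(scores, formula)
    ll1, df1 = _loglik_df(m1, mixed=False)
    ll2, df2 = _loglik_df(m2, mixed=True)
    models = pd.DataFrame({
        "name": ["fixed (population*year)", "mixed (+ colony intercept)"],
        "loglik": [ll1, ll2],
        "df": [df1, df2],
        "aic": [2 * df1 - 2 * ll1, 2 * df2 - 2 * ll2],
    })
    chi2 = max(0.0, 2 * (ll2 - ll1))
    df_diff = df2 - df1
    lrt_p = float(stats.chi2.sf(chi2, df_diff))
    singular = bool(m2.cov_re.iloc[0, 0] < 1e-8) or not m2.converged
    if singular:
        warnings.warn("random-intercept fit is singular or did not converge")

    # deviance tests: drop each fixed term from model 2 (ML LRTs)
    reduced = {
        "year": f"{response} ~ C(population)",
        "population": f"{response} ~ C(year)",
        "population:year": f"{response} ~ C(population) + C(year)",
    }
    rows = []
    for factor, fml in reduced.items():
        ll_r, df_r = _mixed_loglik(scores, fml)
        c = max(0.0, 2 * (ll2 - ll_r))
        d = df2 - df_r
        rows.append((factor, c, d, float(stats.chi2.sf(c, d))))
    factor_tests = pd.DataFrame(rows, columns=["factor", "chi2", "df", "p"])

    tukey = _tukey_year_contrasts(m2, scores)
    preferred = "mixed" if models["aic"].iloc[1] < models["aic"].iloc[0] else "fixed"
    comparison = ModelComparison(models, chi2, df_diff, lrt_p, factor_tests,
                                 tukey, np.nan, preferred, singular,
                                 sigma_u=float(np.sqrt(max(m2.cov_re.iloc[0, 0], 0.0))),
                                 sigma_resid=float(np.sqrt(m2.scale)))

    re = m2.random_effects
    nec_int = pd.Series({k: float(v.iloc[0]) for k, v in re.items()},
                        name="nec_int").sort_index()
    return comparison, nec_int


def _tukey_year_contrasts(mixed_fit, scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise year contrasts of model-based marginal means.

    Marginal mean per year averages the fixed-effect predictions over
    populations; differences use a large-sample studentized-range
    reference (Tukey-style, no Satterthwaite correction).
    """
    design_info = mixed_fit.model.data.design_info
    pops = sorted(scores["population"].unique())
    years = sorted(scores["year"].unique())
    from patsy import dmatrix
    rows = {}
    for y in years:
        grid = pd.DataFrame({"population": pops, "year": [y] * len(pops)})
        X = np.asarray(dmatrix(design_info, grid))
        rows[y] = X.mean(axis=0)
    beta = np.asarray(mixed_fit.fe_params)
    cov = np.asarray(mixed_fit.cov_params())[:len(beta), :len(beta)]
    k = len(years)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            L = rows[years[j]] - rows[years[i]]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            q = abs(est) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, 1e6))
            out.append((years[i], years[j], est, se, p))
    return pd.DataFrame(out, columns=["year_a", "year_b", "estimate", "se", "p_tukey"])


#: leave-one-factor-out fixed formulas; dropping a main factor also drops
#: its interaction (hierarchical reading), dropping "individual" removes
#: the random intercept.
_PARTITION_FACTORS = {
    "year": "C(population)",
    "population": "C(year)",
    "population:year": "C(population) + C(year)",
    "individual": None,
}


def variance_partition(scores: pd.DataFrame,
                       response: str = "transformed") -> VariancePartition:
    """Likelihood-based variance partition over the design factors.

    For each factor f, the raw contribution is the log-likelihood drop
    from removing f from the full mixed model, divided by the change in
    parameter count: C_f = (ll_full − ll_without_f) / (df_full −
    df_without_f), floored at 0.  Percentages renormalise the raw
    contributions to 100.  All models are fitted by ML on the same cases.
    """
    ll_full, df_full = _mixed_loglik(scores, f"{response} ~ C(population) * C(year)")
    rows = []
    for factor, fixed in _PARTITION_FACTORS.items():
        if factor == "individual":
            sub = _fit_fixed(scores, f"{response} ~ C(population) * C(year)")
            ll, df = _loglik_df(sub, mixed=False)
        else:
            ll, df = _mixed_loglik(scores, f"{response} ~ {fixed}")
        d_ll, d_df = ll_full - ll, df_full - df
        if d_df <= 0:
            raise ValueError(f"reduced model for {factor} is not nested")
        rows.append((factor, d_ll, d_df, max(0.0, d_ll / d_df)))
    out = pd.DataFrame(rows, columns=["factor", "delta_loglik", "delta_df", "raw"])
    total = out["raw"].sum()
    out["contribution_pct"] = 100.0 * out["raw"] / total if total > 0 else 0.0
    return VariancePartition(out, ll_full)


# ---------------------------------------------------------------------------
# Field-survey ANOVA
# ---------------------------------------------------------------------------

@dataclass
class SurveyAnova:
    f_stat: float
    p_value: float
    tukey: pd.DataFrame
    group_stats: pd.DataFrame     # population, n, mean, sd


def survey_anova(survey: pd.DataFrame) -> SurveyAnova:
    """One-way ANOVA of in-situ % necrosis across populations + Tukey HSD."""
    groups = {p: g["necrosis_pct"].to_numpy(float)
              for p, g in survey.groupby("population")}
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 observations per population")
    f_stat, p = stats.f_oneway(*groups.values())
    hsd = pairwise_tukeyhsd(survey["necrosis_pct"], survey["population"])
    tukey = pd.DataFrame(hsd.summary().data[1:],
                         columns=hsd.summary().data[0])
    gstats = (survey.groupby("population")["necrosis_pct"]
              .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
              .reset_index())
    return SurveyAnova(float(f_stat), float(p), tukey, gstats)
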