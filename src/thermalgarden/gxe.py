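"""Genotype-by-environment sensitivity analysis (Finlay–Wilkinson style).

The yearly environmental value E_y is the mean phenotype (PC1 fitness
score) over the genotypes present in every year; each genotype's
environmental sensitivity is the OLS slope of its yearly scores on E_y
(Falconer & Mackay).  Averaged over the same complete genotype set that
defines E_y, the slopes have mean exactly 1 — an algebraic identity that
anchors the analysis.  Slope "significance" is summarised against a
randomization null (scores reassigned at random over genotype × year
cells) as exceedance fractions rather than per-slope p-values: 3-point
regressions make the null heavy-tailed, so nominal tests would mislead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EnvironmentalValues:
    values: pd.DataFrame          # year, e_value, sd
    common_genotypes: list[str]

    @property
    def e(self) -> pd.Series:
        return self.values.set_index("year")["e_value"]


def _score_matrix(scores: pd.DataFrame, score_col: str) -> pd.DataFrame:
    """Genotype × year matrix restricted to the complete genotype set."""
    wide = scores.pivot_table(index="colony_id", columns="year",
                              values=score_col)
    return wide.dropna()


def environmental_values(scores: pd.DataFrame,
                         score_col: str = "pc1_score") -> EnvironmentalValues:
    """Yearly environmental values E_y.

    E_y is the mean score per year over the genotypes scored in every
    year, so all years are averaged over the identical genotype set.
    """
    if scores["year"].nunique() < 2:
        raise ValueError("need >= 2 years")
    complete = _score_matrix(scores, score_col)
    if complete.empty:
        raise ValueError("no genotype is present in every year")
    values = pd.DataFrame({
        "year": complete.columns,
        "e_value": complete.mean(axis=0).to_numpy(),
        "sd": complete.std(axis=0, ddof=1).to_numpy(),
        "n_common": len(complete),
    })
    return EnvironmentalValues(values, list(complete.index))


def sensitivity_slopes(scores: pd.DataFrame, env: EnvironmentalValues,
                       score_col: str = "pc1_score") -> pd.DataFrame:
    """Per-genotype sensitivity slope and intercept.

    OLS of each genotype's yearly scores on E_y over the years in
    ``env`` (genotypes missing any of those years are excluded with a
    warning).  Returns a frame with slope, intercept and the
    first-year score used later for classification.
    """
    e = env.e
    if e.std(ddof=0) == 0:
        raise ValueError("environmental values have zero variance")
    wide = scores.pivot_table(index="colony_id", columns="year",
                              values=score_col)[e.index]
    excluded = wide.index[wide.isna().any(axis=1)]
    if len(excluded):
        warnings.warn(f"excluding {len(excluded)} genotypes missing a year")
    wide = wide.dropna()
    ex = e.to_numpy(float)
    exc = ex - ex.mean()
    p = wide.to_numpy(float)
    slopes = (p - p.mean(axis=1, keepdims=True)) @ exc / (exc @ exc)
    intercepts = p.mean(axis=1) - slopes * ex.mean()
    first_year = e.index[0]
    return pd.DataFrame({
        "colony_id": wide.index,
        "slope": slopes,
        "intercept": intercepts,
        "first_year_score": wide[first_year].to_numpy(float),
    }).reset_index(drop=True)


def classify_sensitivity(profiles: pd.DataFrame,
                         null_interval: tuple[float, float]) -> pd.DataFrame:
    """Assign sensitivity categories given a null slope interval.

    A slope inside the null central interval counts as "≈ 0": resistant
    if the genotype's first-year score is below the first-year median
    (low, stable necrosis), hypersensitive if above (high, stable
    necrosis).  Slopes above the interval are sensitive (necrosis
    tracking the worsening environment).  Slopes below the interval
    (negative response) are labelled "other" and flagged.
    """
    lo, hi = null_interval
    median = profiles["first_year_score"].median()
    cats = []
    for _, row in profiles.iterrows():
        if row.slope > hi:
            cats.append("sensitive")
        elif row.slope < lo:
            cats.append("other")
        elif row.first_year_score <= median:
            cats.append("resistant")
        else:
            cats.append("hypersensitive")
    out = profiles.copy()
    out["category"] = cats
    if (out["category"] == "other").any():
        warnings.warn("genotypes with slope below the null interval flagged "
                      "as 'other'")
    return out


@dataclass
class NullSlopeDistribution:
    slopes: np.ndarray            # pooled null slopes over all randomizations
    mean: float
    central_interval: tuple[float, float]   # central 95%
    exceedance_fraction: float    # observed slopes > null mean
    n_randomizations: int
    refit_env: bool


def null_slope_distribution(scores: pd.DataFrame, env: EnvironmentalValues,
                            n_randomizations: int = 10000,
                            seed: int | None = None,
                            score_col: str = "pc1_score",
                            refit_env: bool = True) -> NullSlopeDistribution:
    """Randomization null distribution of sensitivity slopes.

    Each randomization reassigns the pooled scores of the complete
    panel at random to the (genotype, year) cells and refits every
    per-genotype 3-point slope.  By default (``refit_env=True``) the
    environmental values are recomputed as the yearly means of an
    independent random reassignment, so scores and environmental values
    are paired at random: the null is centred at 0 and heavy-tailed,
    because the randomized E_y are means of random scores and can be
    nearly equal, blowing up individual 3-point slopes.  (Recomputing
    E_y from the *same* reassignment would pin the mean slope at
    exactly 1 by the mean-slope identity — no null at all.)
    ``refit_env=False`` keeps the observed E_y fixed instead, giving a
    light-tailed variant.  Reports the pooled null slopes, their mean
    and central 95% interval, and the fraction of observed slopes
    exceeding the null mean.
    """
    if n_randomizations < 100:
        warnings.warn("fewer than 100 randomizations gives a coarse null")
    complete = _score_matrix(scores, score_col)[env.e.index]
    complete = complete.loc[env.common_genotypes]
    p = complete.to_numpy(float)
    g, y = p.shape
    rng = np.random.default_rng(seed)

    flat = p.ravel()
    order = np.argsort(rng.random((n_randomizations, g * y)), axis=1)
    perm = flat[order].reshape(n_randomizations, g, y)

    if refit_env:
        order2 = np.argsort(rng.random((n_randomizations, g * y)), axis=1)
        e = flat[order2].reshape(n_randomizations, g, y).mean(axis=1)  # (R, y)
    else:
        e = np.broadcast_to(env.e.to_numpy(float), (n_randomizations, y))
    ec = e - e.mean(axis=1, keepdims=True)
    var_e = np.einsum("ry,ry->r", ec, ec)
    if (var_e == 0).any():
        bad = var_e == 0                           # degenerate permutation
        var_e = np.where(bad, np.nan, var_e)
    pc = perm - perm.mean(axis=2, keepdims=True)
    null = np.einsum("rgy,ry->rg", pc, ec) / var_e[:, None]
    null = null[np.isfinite(null)]

    obs = sensitivity_slopes(scores, env, score_col)["slope"].to_numpy()
    mean = float(null.mean())
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    exceed = float((obs > mean).mean())
    return NullSlopeDistribution(null, mean, ci, exceed, n_randomizations,
                                 refit_env)
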