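"""Within-habitat species comparisons and trait-variability (CV%) summaries.

Species are compared within each habitat by Gaussian linear models (fitted by
maximum likelihood, so likelihood-ratio tests are available), followed by
Tukey HSD multiple comparisons with a compact-letter display. Trait
variability is summarized as the coefficient of variation, CV% = 100 * sd /
|mean|, computed on the Kelvin scale for the temperature traits (Topt, ULT)
so that ratios are taken on a physically meaningful absolute scale.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthetic import TEMPERATURE_TRAITS

KELVIN_OFFSET = 273.15


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gaussian linear models and LRT
# ---------------------------------------------------------------------------

@dataclass
class LinearModelFit:
    """Gaussian linear model of a trait on a group factor (ML fit)."""

    response: str
    levels: list
    values: np.ndarray
    groups: np.ndarray
    result: object  # statsmodels RegressionResults
    n_mean_params: int
    design: np.ndarray = field(repr=False, default=None)

    @property
    def logLik(self) -> float:
        return float(self.result.llf)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    def group_stats(self) -> pd.DataFrame:
        df = pd.DataFrame({"value": self.values, "group": self.groups})
        g = df.groupby("group")["value"]
        return pd.DataFrame({"n": g.size(), "mean": g.mean()}).loc[self.levels]


def fit_lm(values, groups, response: str = "trait") -> LinearModelFit:
    """One-way Gaussian linear model. Requires >= 2 groups, >= 2 obs per group."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise StatsError("need at least 2 groups")
    for lv in levels:
        if np.sum(groups == lv) < 2:
            raise StatsError(f"group {lv!r} has fewer than 2 observations")
    X = np.column_stack([np.ones(len(values))]
                        + [(groups == lv).astype(float) for lv in levels[1:]])
    result = sm.OLS(values, X).fit()
    return LinearModelFit(response, levels, values, groups, result,
                          n_mean_params=len(levels), design=X)


def intercept_only(values, response: str = "trait") -> LinearModelFit:
    """Null model: a single mean for all observations (for LRTs)."""
    values = np.asarray(values, dtype=float)
    X = np.ones((len(values), 1))
    result = sm.OLS(values, X).fit()
    return LinearModelFit(response, ["all"], values,
                          np.repeat("all", len(values)), result,
                          n_mean_params=1, design=X)


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt(full: LinearModelFit, reduced: LinearModelFit) -> LRTResult:
    """Likelihood-ratio test of nested Gaussian linear models (chi-square asymptotics)."""
    if len(full.values) != len(reduced.values) or not np.allclose(
            full.values, reduced.values):
        raise StatsError("models must be fitted to the same data")
    if reduced.n_mean_params > full.n_mean_params:
        raise StatsError("reduced model has more parameters than the full model")
    # nesting: the reduced design must lie in the column span of the full design
    proj, *_ = np.linalg.lstsq(full.design, reduced.design, rcond=None)
    if not np.allclose(full.design @ proj, reduced.design, atol=1e-8):
        raise StatsError("models are not nested")
    chi2 = max(2.0 * (full.logLik - reduced.logLik), 0.0)
    df = full.n_mean_params - reduced.n_mean_params
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    return LRTResult(chi2, df, p)


# ---------------------------------------------------------------------------
# Tukey HSD and compact-letter display
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    table: pd.DataFrame  # level_i, level_j, mean_diff, q_stat, p_adj
    letters: dict  # level -> compact letter string
    alpha: float
    zero_mse: bool = False


def _compact_letters(levels_by_mean: Sequence, significant) -> dict:
    """Insert-and-absorb compact letter display.

    Levels sharing a letter are not significantly different. ``significant``
    maps a frozenset pair to a bool.
    """
    groups: list[set] = []
    for lv in levels_by_mean:
        placed = False
        for grp in groups:
            if all(not significant[frozenset((lv, m))] for m in grp):
                grp.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    groups = [g for g in groups
              if not any(g < other for other in groups)]  # absorb subsets
    letters = {lv: "" for lv in levels_by_mean}
    for letter, grp in zip(string.ascii_lowercase, groups):
        for lv in grp:
            letters[lv] += letter
    return letters


def tukey_hsd(fit: LinearModelFit, alpha: float = 0.05) -> TukeyResult:
    """Tukey(-Kramer) HSD over all group pairs, with a compact-letter display.

    q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)), with p-values from
    the studentized-range distribution (k groups, residual df).
    """
    stats = fit.group_stats()
    k = len(fit.levels)
    n_total = len(fit.values)
    df_resid = n_total - k
    mse = float(fit.result.ssr / df_resid)
    zero_mse = mse <= 0
    if zero_mse:
        warnings.warn("zero residual variance: all unequal pairs flagged significant")
    rows = []
    sig = {}
    for a, b in itertools.combinations(fit.levels, 2):
        diff = float(stats.loc[b, "mean"] - stats.loc[a, "mean"])
        if zero_mse:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / stats.loc[a, "n"] + 1.0 / stats.loc[b, "n"]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_resid))
        rows.append({"level_i": a, "level_j": b, "mean_diff": diff,
                     "q_stat": q, "p_adj": min(max(p, 0.0), 1.0)})
        sig[frozenset((a, b))] = rows[-1]["p_adj"] < alpha
    order = stats.sort_values("mean", ascending=False).index.tolist()
    letters = _compact_letters(order, sig)
    return TukeyResult(pd.DataFrame(rows), letters, alpha, zero_mse)


# ---------------------------------------------------------------------------
# CV% summaries
# ---------------------------------------------------------------------------

@dataclass
class CVSummary:
    trait: str
    per_species: pd.Series  # CV% per species
    mean_cv: float
    sd_cv: float
    kelvin_applied: bool
    undefined_species: list


def cv_summary(table: pd.DataFrame, trait: str,
               min_individuals: int = 2) -> CVSummary:
    """Per-species CV% of one trait, then mean +- SD across species.

    Temperature traits (Topt, ULT) are converted from Celsius to Kelvin
    before the ratio. Species whose mean is zero get an undefined (NaN) CV
    and are flagged. CV uses |mean| so the statistic is non-negative for
    negative-valued traits (e.g. slope curvature).
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise StatsError(f"no rows for trait {trait!r}")
    kelvin = trait in TEMPERATURE_TRAITS
    counts = sub.groupby("species")["value"].size()
    too_few = counts[counts < min_individuals]
    if len(too_few):
        raise StatsError(
            f"species with fewer than {min_individuals} individuals for "
            f"{trait!r}: {list(too_few.index)}")
    undefined = []
    cvs = {}
    for sp, vals in sub.groupby("species")["value"]:
        x = vals.to_numpy(float) + (KELVIN_OFFSET if kelvin else 0.0)
        mu = x.mean()
        if mu == 0:
            undefined.append(sp)
            cvs[sp] = np.nan
        else:
            cvs[sp] = 100.0 * x.std(ddof=1) / abs(mu)
    per_species = pd.Series(cvs, name=trait).sort_index()
    valid = per_species.dropna()
    return CVSummary(trait, per_species, float(valid.mean()),
                     float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
                     kelvin, undefined)


def cv_table(table: pd.DataFrame, traits: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Mean +- SD of per-species CV% for each trait, sorted by mean CV."""
    if traits is None:
        traits = sorted(table["trait"].unique())
    rows = []
    for trait in traits:
        s = cv_summary(table, trait)
        rows.append({"trait": trait, "mean_cv_pct": s.mean_cv,
                     "sd_cv_pct": s.sd_cv, "kelvin_applied": s.kelvin_applied})
    return pd.DataFrame(rows).sort_values("mean_cv_pct", ignore_index=True)
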