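"""Cohort-level models: mixed-effects fits, ANOVA with Tukey HSD, t-tests.

The central model is a linear mixed-effects regression of a per-session
metric on diet (or diet-switch condition) crossed with meal phase, with a
random intercept per mouse to absorb the dependence among repeated sessions
of the same animal: Value ~ Diet * MealPhase + (1 | Mouse).  Estimation is
REML via statsmodels ``mixedlm``; fixed-effect p-values are Wald z tests
(the convention is recorded in the result metadata).  Conditions observed
in fewer than two unique mice are excluded before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "StatResult", "fit_lme", "anova_tukey", "t_tests"]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random-effect layout of a mixed model on a tidy table."""

    response: str = "value"
    fixed: tuple[str, ...] = ("Diet", "MealPhase")  # crossed (interaction included)
    grouping: str = "Mouse"
    reference_levels: dict = field(default_factory=dict)

    def formula(self) -> str:
        terms = []
        for f in self.fixed:
            ref = self.reference_levels.get(f)
            terms.append(f"C({f}, Treatment({ref!r}))" if ref is not None else f"C({f})")
        return f"{self.response} ~ " + " * ".join(terms)

    def describe(self) -> str:
        return f"{self.response} ~ {' * '.join(self.fixed)} + (1|{self.grouping})"


@dataclass
class StatResult:
    """Estimates, uncertainties and p-values of one fitted analysis."""

    kind: str  # lme | anova | ttest
    formula: str
    estimates: dict  # name -> (estimate, se)
    p_values: dict  # name -> p
    contrasts: Optional[pd.DataFrame] = None  # Tukey table
    n_obs: int = 0
    n_groups: int = 0
    converged: bool = True
    excluded: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"term": k, "estimate": est, "se": se,
                 "p": self.p_values.get(k, np.nan)}
                for k, (est, se) in self.estimates.items()]
        return pd.DataFrame(rows)


def _exclude_sparse_conditions(
    table: pd.DataFrame, factors: Sequence[str], group: str, min_mice: int = 2
) -> tuple[pd.DataFrame, list]:
    """Drop factor levels observed in fewer than ``min_mice`` unique mice."""
    excluded = []
    for f in factors:
        counts = table.groupby(f, observed=True)[group].nunique()
        bad = counts[counts < min_mice].index.tolist()
        if bad:
            logger.warning("excluding %s level(s) with < %d unique mice: %s", f, min_mice, bad)
            excluded.extend((f, lvl) for lvl in bad)
            table = table[~table[f].isin(bad)]
    return table, excluded


def fit_lme(table: pd.DataFrame, spec: ModelSpec | None = None, reml: bool = True) -> StatResult:
    """Fit ``response ~ fixed1 * fixed2 + (1 | group)`` by REML.

    Wald z p-values per fixed-effect coefficient; singular or non-converged
    fits are returned with ``converged=False`` rather than silently refit.
    """
    spec = spec or ModelSpec()
    needed = [spec.response, spec.grouping, *spec.fixed]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    data = table.dropna(subset=[spec.response]).copy()
    data, excluded = _exclude_sparse_conditions(data, spec.fixed, spec.grouping)
    if data[spec.grouping].nunique() < 2:
        raise ValueError("need >= 2 unique mice to fit a mixed model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula(), data, groups=data[spec.grouping])
        fit = model.fit(reml=reml)
    converged = bool(getattr(fit, "converged", True))
    estimates = {name: (float(fit.params[name]), float(fit.bse[name]))
                 for name in fit.fe_params.index}
    p_values = {name: float(fit.pvalues[name]) for name in fit.fe_params.index}
    return StatResult(
        kind="lme", formula=spec.describe(), estimates=estimates, p_values=p_values,
        n_obs=int(fit.nobs), n_groups=int(data[spec.grouping].nunique()),
        converged=converged, excluded=excluded,
        meta={"method": "REML" if reml else "ML", "df": "Wald z (normal approximation)",
              "group_var": float(np.asarray(fit.cov_re).ravel()[0]),
              "resid_var": float(fit.scale)},
    )


def anova_tukey(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    design: str = "one-way",
    alpha: float = 0.05,
) -> StatResult:
    """ANOVA (type II) with Tukey HSD pairwise contrasts.

    One-way uses the single factor's levels; two-way fits both factors plus
    their interaction and runs Tukey over the factor-cell combinations.
    """
    if design not in ("one-way", "two-way"):
        raise ValueError("design must be 'one-way' or 'two-way'")
    if design == "one-way" and len(factors) != 1:
        raise ValueError("one-way design takes exactly one factor")
    if design == "two-way" and len(factors) != 2:
        raise ValueError("two-way design takes exactly two factors")
    data = table.dropna(subset=[response, *factors]).copy()
    cells = data.groupby(list(factors), observed=True)[response].count()
    if (cells < (2 if design == "two-way" else 1)).any() or cells.empty:
        bad = cells[cells < (2 if design == "two-way" else 1)]
        raise ValueError(f"empty or singleton design cells: {bad.index.tolist()}")
    rhs = " * ".join(f"C({f})" for f in factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(f"{response} ~ {rhs}", data=data).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
    p_values, estimates = {}, {}
    for term in aov.index:
        if term == "Residual":
            continue
        p_values[term] = float(aov.loc[term, "PR(>F)"])
        estimates[term] = (float(aov.loc[term, "F"]), float("nan"))
    cell_labels = (data[factors[0]].astype(str) if design == "one-way"
                   else data[list(factors)].astype(str).agg(":".join, axis=1))
    tk = pairwise_tukeyhsd(data[response].to_numpy(), cell_labels.to_numpy(), alpha=alpha)
    contrasts = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return StatResult(
        kind="anova", formula=f"{response} ~ {' * '.join(factors)}",
        estimates=estimates, p_values=p_values, contrasts=contrasts,
        n_obs=int(len(data)), n_groups=int(cell_labels.nunique()),
        meta={"design": design, "anova_table": aov, "alpha": alpha},
    )


def t_tests(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    equal_var: bool = True,
) -> StatResult:
    """Two-tailed t-test; Student (equal-variance) by default for unpaired."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs aligned samples of equal length")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 2:
            raise ValueError("need n >= 2 pairs")
        d = x - y
        if np.all(d == d[0]):
            # zero-variance differences: t = 0 (p = 1) for identical samples
            stat = 0.0 if d[0] == 0 else np.inf * np.sign(d[0])
            res = type("R", (), {"statistic": stat,
                                 "pvalue": 1.0 if d[0] == 0 else 0.0})()
        else:
            res = sps.ttest_rel(x, y)
        df = x.size - 1
    else:
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            raise ValueError("need n >= 2 per group")
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        df = float(res.df) if hasattr(res, "df") else x.size + y.size - 2
    name = "paired t" if paired else ("Student t" if equal_var else "Welch t")
    return StatResult(
        kind="ttest", formula=name,
        estimates={"t": (float(res.statistic), float("nan")),
                   "mean_diff": (float(np.mean(x) - np.mean(y)), float("nan"))},
        p_values={"t": float(res.pvalue)},
        n_obs=int(x.size + y.size), n_groups=2,
        meta={"df": float(df), "paired": paired, "equal_var": equal_var},
    )
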