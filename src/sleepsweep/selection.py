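"""Quantitative genetics of the selection response.

Cumulative selection differentials and responses, realized heritability by
regression of cumulative response on cumulative differential, coefficient
of environmental variation, and long-vs-short divergence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def cv_e(values) -> float:
    """Coefficient of environmental variation: 100 * SD / mean.

    Sample SD (ddof=1) of the within-population trait values divided by
    their mean, as a percentage.  NaN if the mean is zero.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    mu = values.mean()
    if mu == 0:
        return float("nan")
    return 100.0 * values.std(ddof=1) / mu


@dataclass
class SelectionSeries:
    """Per-generation differentials/responses and their prefix sums.

    ``table`` has one row per generation with columns ``generation``,
    ``mean``, ``parent_mean``, ``S`` (parent mean - population mean, the
    differential applied *at* that generation), ``R`` (that generation's
    mean minus the previous generation's), ``cum_S`` (sum of differentials
    applied before the generation) and ``cum_R`` (mean minus the
    generation-0 mean).  For unselected controls the cumulative response
    is conventionally a cumulative *difference*; same arithmetic.
    """

    table: pd.DataFrame

    @property
    def cum_S(self) -> np.ndarray:
        return self.table["cum_S"].to_numpy()

    @property
    def cum_R(self) -> np.ndarray:
        return self.table["cum_R"].to_numpy()


def cumulative_series(summaries: pd.DataFrame) -> SelectionSeries:
    """Build the cumulative S/R series from per-generation summaries.

    ``summaries`` needs columns ``generation``, ``mean`` and
    ``parent_mean`` (mean of the selected parents; NaN allowed for the
    final generation, where no parents are chosen).  Generations must be
    consecutive integers.
    """
    df = summaries.sort_values("generation").reset_index(drop=True)
    gens = df["generation"].to_numpy()
    if np.any(np.diff(gens) != 1):
        raise ValueError("generations must be consecutive with no gaps")
    mean = df["mean"].to_numpy(dtype=float)
    parent = df["parent_mean"].to_numpy(dtype=float)

    S = parent - mean
    R = np.concatenate(([0.0], np.diff(mean)))
    # cum_S at generation t sums the differentials applied in generations < t
    cum_S = np.concatenate(([0.0], np.nancumsum(S)[:-1]))
    cum_R = mean - mean[0]
    out = df[["generation", "mean", "parent_mean"]].copy()
    out["S"] = S
    out["R"] = R
    out["cum_S"] = cum_S
    out["cum_R"] = cum_R
    return SelectionSeries(out)


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    p_value: float
    intercept: float = 0.0
    through_origin: bool = True


def realized_heritability(series: SelectionSeries,
                          through_origin: bool = True) -> HeritabilityEstimate:
    """Realized h^2: slope of cumulative response on cumulative differential.

    Fitted through the origin by default (both sums are zero at generation
    0 by construction); set ``through_origin=False`` for the ordinary
    regression with an intercept.
    """
    x = series.cum_S
    y = series.cum_R
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least three generations")
    if np.allclose(x, 0):
        raise ValueError("cumulative differential is identically zero")

    if through_origin:
        sxx = float(np.dot(x, x))
        slope = float(np.dot(x, y)) / sxx
        resid = y - slope * x
        dof = x.size - 1
        sigma2 = float(np.dot(resid, resid)) / dof
        se = np.sqrt(sigma2 / sxx)
        tval = slope / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tval), dof) if np.isfinite(tval) else 0.0
        return HeritabilityEstimate(slope, float(se), float(p))
    res = stats.linregress(x, y)
    return HeritabilityEstimate(float(res.slope), float(res.stderr),
                                float(res.pvalue), intercept=float(res.intercept),
                                through_origin=False)


def divergence(long_means, short_means) -> float:
    """Mean(long replicates) - mean(short replicates), in trait units."""
    long_means = np.asarray(long_means, dtype=float)
    short_means = np.asarray(short_means, dtype=float)
    if long_means.size == 0 or short_means.size == 0:
        raise ValueError("need at least one replicate mean per scheme")
    return float(long_means.mean() - short_means.mean())


def generation_summaries(phenotypes: pd.DataFrame, trait: str = "phenotype",
                         by_sex: bool = False) -> pd.DataFrame:
    """Per population x generation summary rows from fly-level phenotypes.

    ``phenotypes`` must carry columns ``population``, ``generation``,
    ``sex``, ``is_parent`` and the trait column.  Sexes are pooled unless
    ``by_sex``.
    """
    keys = ["population", "generation"] + (["sex"] if by_sex else [])

    def _summ(grp: pd.DataFrame) -> pd.Series:
        sel = grp[grp["is_parent"]]
        return pd.Series({
            "mean": grp[trait].mean(),
            "sd": grp[trait].std(ddof=1),
            "cv_e": cv_e(grp[trait]) if grp[trait].mean() != 0 else np.nan,
            "parent_mean": sel[trait].mean() if len(sel) else np.nan,
            "n": len(grp),
            "n_parents": len(sel),
        })

    out = phenotypes.groupby(keys, sort=True).apply(_summ, include_groups=False)
    return out.reset_index()


def selection_report(summaries: pd.DataFrame) -> pd.DataFrame:
    """Realized-h^2 table: one row per population in the summary frame."""
    rows = []
    for pop, grp in summaries.groupby("population", sort=True):
        series = cumulative_series(grp)
        for origin in (True, False):
            est = realized_heritability(series, through_origin=origin)
            rows.append({
                "population": pop,
                "through_origin": origin,
                "h2": est.h2,
                "se": est.se,
                "p_value": est.p_value,
                "intercept": est.intercept,
            })
    return pd.DataFrame(rows)
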