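"""Static allometry: log-log regressions and residual-variance selection indices.

A character growing allometrically with body size follows a power law
y = c * x^b, linear on ln-ln axes. Two quantities summarize a population:
the fitted slope b (the growth pattern) and the variance of residuals
around the line. A tightly canalized character — one under strong
stabilizing selection — shows a small residual variance within populations
and little slope dispersion among them; a weakly selected character shows
the reverse. This module fits the regressions and performs the variance
and slope comparisons built on them.

Head width (HW) is the default body-size covariate throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AllometricFit",
    "SummaryStat",
    "ln_transform",
    "fit_allometry",
    "residual_variance_by_population",
    "summarize_across_populations",
    "slope_variance_across_populations",
    "variance_ratio_test",
    "bonferroni",
    "paired_t_test",
    "two_sample_t_from_summary",
    "slope_homogeneity_test",
    "slope_latitude_correlation",
]

_CHARACTER_VOCAB = {"HW", "HTL", "FTSL", "HTSL", "MTSL", "FTS", "HTS", "MTS"}


@dataclass(frozen=True)
class AllometricFit:
    """One OLS fit of ln(character) on ln(HW) for one group."""

    group: str
    level: str  # "population" or "nest"
    character: str
    slope: float
    intercept: float
    residuals: np.ndarray
    residual_variance: float  # denominator n - 2
    n: int


@dataclass(frozen=True)
class SummaryStat:
    """A printed-style summary: mean +/- SD with sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def ln_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform every length; lengths must be positive.

    Returns a copy with ``length_mm`` replaced by ``ln_length`` and the
    original unit recorded in ``DataFrame.attrs['original_unit']``.
    """
    bad = table[table["length_mm"] <= 0]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            "nonpositive length for individual "
            f"{row['individual']!r}, character {row['character']!r}: "
            f"{row['length_mm']}"
        )
    out = table.copy()
    out["ln_length"] = np.log(out.pop("length_mm"))
    out.attrs["original_unit"] = "mm"
    return out


def _pivot(table: pd.DataFrame, y: str, x: str) -> pd.DataFrame:
    value_col = "ln_length" if "ln_length" in table.columns else "length_mm"
    wide = table.pivot_table(
        index=["population", "nest", "individual"],
        columns="character",
        values=value_col,
        aggfunc="first",
    ).reset_index()
    missing = [c for c in (y, x) if c not in wide.columns]
    if missing:
        raise ValueError(f"character(s) not present in table: {missing}")
    return wide.dropna(subset=[y, x])


def fit_allometry(
    table: pd.DataFrame,
    y: str,
    x: str = "HW",
    group_by: str = "population",
) -> list[AllometricFit]:
    """OLS of ln(y) on ln(x), one fit per group (population or nest).

    The input is expected ln-transformed (:func:`ln_transform`); residual
    variance uses denominator n - 2. Groups need >= 3 individuals and a
    non-degenerate covariate.
    """
    if group_by not in ("population", "nest"):
        raise ValueError("group_by must be 'population' or 'nest'")
    wide = _pivot(table, y, x)
    fits: list[AllometricFit] = []
    for group, sub in wide.groupby(group_by, sort=True):
        xv = sub[x].to_numpy(float)
        yv = sub[y].to_numpy(float)
        n = len(xv)
        if n < 3:
            raise ValueError(f"group {group!r}: need >= 3 individuals, got {n}")
        sxx = np.sum((xv - xv.mean()) ** 2)
        if sxx == 0:
            raise ValueError(f"group {group!r}: covariate {x!r} has zero variance")
        slope = float(np.sum((xv - xv.mean()) * (yv - yv.mean())) / sxx)
        intercept = float(yv.mean() - slope * xv.mean())
        resid = yv - (intercept + slope * xv)
        fits.append(
            AllometricFit(
                group=str(group),
                level=group_by,
                character=y,
                slope=slope,
                intercept=intercept,
                residuals=resid,
                residual_variance=float(np.sum(resid**2) / (n - 2)),
                n=n,
            )
        )
    return fits


def residual_variance_by_population(
    fits_by_character: dict[str, list[AllometricFit]],
    scale: float = 1.0,
) -> pd.DataFrame:
    """Residual-variance table: characters x populations, with margins.

    Returns one row per character, one column per population, plus
    ``mean`` and ``sd`` columns holding the across-population margin
    (sd uses denominator n - 1). ``scale`` multiplies all variances
    (e.g. 1e5 for display in units of 1e-5).
    """
    rows = {}
    for character, fits in fits_by_character.items():
        rows[character] = {f.group: f.residual_variance * scale for f in fits}
    table = pd.DataFrame(rows).T
    table["mean"] = table.mean(axis=1)
    table["sd"] = table.drop(columns="mean").std(axis=1, ddof=1)
    return table


def summarize_across_populations(values) -> SummaryStat:
    """Across-population mean +/- SD (ddof=1) of per-population values."""
    arr = np.asarray(values, dtype=float)
    return SummaryStat(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr)
    )


def slope_variance_across_populations(fits: list[AllometricFit]) -> float:
    """Sample variance (denominator n - 1) of the per-population slopes."""
    if len(fits) < 2:
        raise ValueError("need slopes from >= 2 populations")
    slopes = np.array([f.slope for f in fits])
    return float(slopes.var(ddof=1))


def variance_ratio_test(
    v1: float, df1: int, v2: float, df2: int
) -> tuple[float, float]:
    """Two-sided F test of two variances; F = v1/v2 as ordered by caller.

    p = 2 * min(P[F <= f], P[F >= f]), capped at 1. A zero denominator
    yields an explicit infinite F with p = 0.
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be >= 0")
    if v2 == 0:
        return math.inf, 0.0
    f = v1 / v2
    cdf = stats.f.cdf(f, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def paired_t_test(values_a, values_b) -> tuple[float, int, float]:
    """Classical paired t on per-population pairs; df = n - 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diff = a - b
    if np.var(diff, ddof=1) == 0:
        if np.all(diff == 0):  # identical vectors: no difference at all
            return 0.0, len(a) - 1, 1.0
        raise ValueError("differences have zero variance; t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def two_sample_t_from_summary(
    a: SummaryStat, b: SummaryStat
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from printed summaries; df = na + nb - 2."""
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in each sample")
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both SDs zero; t undefined")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(res.statistic), a.n + b.n - 2, float(res.pvalue)


def slope_homogeneity_test(
    table: pd.DataFrame, character: str, x: str = "HW"
) -> tuple[float, tuple[int, int], float]:
    """ANCOVA-style F test for slope heterogeneity among populations.

    Compares the full linear model (per-population slopes and intercepts)
    against the reduced common-slope model by residual sum of squares:
    F = ((RSS_r - RSS_f)/(k-1)) / (RSS_f/(n-2k)) for k populations.
    """
    import statsmodels.formula.api as smf

    wide = _pivot(table, character, x).rename(
        columns={character: "_y", x: "_x"}
    )
    k = wide["population"].nunique()
    if k < 2:
        raise ValueError("need >= 2 populations for a slope-heterogeneity test")
    counts = wide.groupby("population").size()
    thin = counts[counts < 3]
    if len(thin):
        raise ValueError(
            f"population {thin.index[0]!r} has too few individuals "
            f"({thin.iloc[0]}) for a per-population slope"
        )
    full = smf.ols("_y ~ C(population) * _x", data=wide).fit()
    reduced = smf.ols("_y ~ C(population) + _x", data=wide).fit()
    df_num = k - 1
    df_den = int(full.df_resid)
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), (df_num, df_den), p


def slope_latitude_correlation(
    fits: list[AllometricFit], latitudes: dict[str, float]
) -> tuple[float, float]:
    """Pearson correlation between population slopes and site latitudes."""
    if len(fits) < 3:
        raise ValueError("need >= 3 populations")
    slopes = np.array([f.slope for f in fits])
    lats = np.array([latitudes[f.group] for f in fits])
    if np.var(slopes) == 0 or np.var(lats) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(slopes, lats)
    return float(r), float(p)
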