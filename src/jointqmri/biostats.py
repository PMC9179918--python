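"""Robust statistics for factorial joint-health studies.

The central procedure is the heteroscedastic two-way ANOVA for trimmed means
(Wilcox): in a J x K design, each cell contributes its 20%-trimmed mean, its
winsorized variance, and its effective sample size h = n - 2*floor(trim*n).
Main effects and the interaction are tested with Johansen-type quadratic
forms

    Q = (C m)' (C V C')^{-1} (C m),

where m stacks the cell trimmed means, V is the diagonal matrix of squared
standard errors v_jk = (n-1) s_w^2 / (h (h-1)), and C is the difference
contrast matrix of the effect.  P-values come from the adjusted chi-square
critical value c = q + q/(2k) * A * (1 + 3q/(k+2)) with
A = sum_j R_jj^2/(h_j - 1), R = V C'(C V C')^{-1} C, inverted exactly in q
(the adjustment is quadratic in q).  With trim = 0 the procedure reduces to
the classical heteroscedastic (Welch-Johansen) factorial ANOVA.

Also provided: the two-sample t-test power function based on the noncentral
t distribution, its inverse (effect size achieving a target power),
median/min/max/IQR descriptives, and ordinal stage-frequency tables for
heat-map style summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grids import DegenerateDataError, ParameterError, ScoreRecord, records_to_frame

__all__ = [
    "TrimmedStats",
    "TrimmedAnovaResult",
    "PowerSpec",
    "trimmed_mean_stats",
    "trimmed_two_way_anova",
    "power_two_sample_t",
    "effect_size_from_power",
    "descriptive_summary",
    "stage_frequency_table",
]


# --------------------------------------------------------------------------
# trimmed / winsorized building blocks
# --------------------------------------------------------------------------

class TrimmedStats(NamedTuple):
    trimmed_mean: float
    winsorized_variance: float
    h: int  # effective sample size after trimming


def trimmed_mean_stats(x, trim: float = 0.2) -> TrimmedStats:
    """Trimmed mean, winsorized variance, and effective df of a sample.

    ``floor(trim * n)`` order statistics are removed from each tail for the
    mean and clamped to the remaining extremes for the winsorized variance.
    ``trim=0`` gives the ordinary mean and variance.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("empty sample")
    if not 0 <= trim < 0.5:
        raise ParameterError("trim fraction must lie in [0, 0.5)")
    n = x.size
    g = int(math.floor(trim * n))
    if n - 2 * g < 1:
        raise ParameterError(f"trimming {g} per tail leaves no data (n={n})")
    xs = np.sort(x)
    tmean = float(xs[g : n - g].mean())
    w = xs.copy()
    w[:g] = xs[g]
    w[n - g :] = xs[n - g - 1]
    wvar = float(w.var(ddof=1)) if n > 1 else 0.0
    return TrimmedStats(tmean, wvar, n - 2 * g)


# --------------------------------------------------------------------------
# two-way trimmed-means ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimmedAnovaResult:
    """Q statistics and p-values for factor A, factor B, and A x B."""

    q_a: float
    q_b: float
    q_ab: float
    p_a: float
    p_b: float
    p_ab: float
    trim: float
    levels_a: tuple
    levels_b: tuple


def _difference_contrasts(j: int) -> np.ndarray:
    c = np.zeros((j - 1, j))
    for i in range(j - 1):
        c[i, i] = 1.0
        c[i, i + 1] = -1.0
    return c


def _johansen(C: np.ndarray, means: np.ndarray, v: np.ndarray, h: np.ndarray):
    """Q statistic and adjusted-chi-square p-value for contrast C."""
    V = np.diag(v)
    CV = C @ V @ C.T
    try:
        inv = np.linalg.inv(CV)
    except np.linalg.LinAlgError as e:
        raise DegenerateDataError(
            "contrast covariance is singular (zero winsorized variance in the cells)"
        ) from e
    m = means[:, None]
    q = float((m.T @ C.T @ inv @ C @ m)[0, 0])
    R = V @ C.T @ inv @ C
    a = float(np.sum(np.diag(R) ** 2 / (h - 1.0)))
    k = C.shape[0]
    # invert c(q*) = q* (1 + A/2k) + q*^2 3A/(2k(k+2)) = Q for the chi-square
    # quantile q*, then p = P(chi2_k > q*)
    quad = 3.0 * a / (2.0 * k * (k + 2.0))
    lin = 1.0 + a / (2.0 * k)
    if quad == 0:
        qstar = q / lin
    else:
        qstar = (-lin + math.sqrt(lin * lin + 4.0 * quad * q)) / (2.0 * quad)
    return q, float(stats.chi2.sf(qstar, k))


def _as_frame(data, response, factor_a, factor_b) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data
    else:  # sequence of ScoreRecords
        df = records_to_frame(list(data))
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ParameterError(f"column {col!r} not found in data")
    return df


def trimmed_two_way_anova(
    data: Union[pd.DataFrame, Sequence[ScoreRecord]],
    response: str = "value",
    factor_a: str = "group",
    factor_b: str = "time_days",
    trim: float = 0.2,
    n_boot: Optional[int] = None,
    seed: Optional[int] = None,
) -> TrimmedAnovaResult:
    """Two-way heteroscedastic ANOVA for trimmed means with interaction.

    ``data`` is a tidy table (or ScoreRecord list) with one row per
    observation.  Every (A, B) cell must be non-empty with at least 2
    observations surviving trimming.  Set ``n_boot`` for a seeded
    percentile-bootstrap p-value (cells centred at their trimmed means)
    instead of the adjusted critical-value approximation.
    """
    df = _as_frame(data, response, factor_a, factor_b)
    levels_a = tuple(pd.unique(df[factor_a]))
    levels_b = tuple(pd.unique(df[factor_b]))
    J, K = len(levels_a), len(levels_b)
    if J < 2 or K < 2:
        raise ParameterError(f"both factors need >= 2 levels (got {J} x {K})")

    cells = []
    for a in levels_a:
        for b in levels_b:
            x = df.loc[(df[factor_a] == a) & (df[factor_b] == b), response].to_numpy(float)
            if x.size == 0:
                raise ParameterError(f"empty cell: {factor_a}={a!r}, {factor_b}={b!r}")
            st = trimmed_mean_stats(x, trim)
            if st.h < 2:
                raise ParameterError(
                    f"cell {factor_a}={a!r}, {factor_b}={b!r} has h={st.h} < 2 after trimming"
                )
            cells.append((x, st))

    if all(st.winsorized_variance == 0.0 for _, st in cells):
        raise DegenerateDataError("all cells have zero winsorized variance; Q is undefined")

    means = np.array([st.trimmed_mean for _, st in cells])
    h = np.array([st.h for _, st in cells], dtype=float)
    n = np.array([x.size for x, _ in cells], dtype=float)
    v = np.array(
        [(x.size - 1) * st.winsorized_variance / (st.h * (st.h - 1.0)) for x, st in cells]
    )

    cj = _difference_contrasts(J)
    ck = _difference_contrasts(K)
    ij = np.ones((1, J))
    ik = np.ones((1, K))
    CA = np.kron(cj, ik)
    CB = np.kron(ij, ck)
    CAB = np.kron(cj, ck)

    qs, ps = {}, {}
    for name, C in (("A", CA), ("B", CB), ("AB", CAB)):
        qs[name], ps[name] = _johansen(C, means, v, h)

    if n_boot is not None:
        rng = np.random.default_rng(seed)
        centred = [x - st.trimmed_mean for x, st in cells]
        exceed = {name: 0 for name in qs}
        for _ in range(int(n_boot)):
            bmeans, bv = [], []
            for x in centred:
                xb = rng.choice(x, size=x.size, replace=True)
                st = trimmed_mean_stats(xb, trim)
                bmeans.append(st.trimmed_mean)
                bv.append((x.size - 1) * st.winsorized_variance / (st.h * (st.h - 1.0)))
            bmeans = np.asarray(bmeans)
            bv = np.asarray(bv)
            for name, C in (("A", CA), ("B", CB), ("AB", CAB)):
                try:
                    qb, _ = _johansen(C, bmeans, bv, h)
                except DegenerateDataError:
                    continue
                if qb >= qs[name]:
                    exceed[name] += 1
        ps = {name: (exceed[name] + 1) / (int(n_boot) + 1) for name in qs}

    return TrimmedAnovaResult(
        q_a=qs["A"], q_b=qs["B"], q_ab=qs["AB"],
        p_a=ps["A"], p_b=ps["B"], p_ab=ps["AB"],
        trim=trim, levels_a=levels_a, levels_b=levels_b,
    )


# --------------------------------------------------------------------------
# power / effect size for the two-sample t test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a two-sample t test power calculation."""

    n_per_group: int
    alpha: float = 0.05
    power: float = 0.8
    sides: str = "two-sided"
    d: Optional[float] = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if not self.alpha < self.power < 1:
            raise ParameterError("power must lie in (alpha, 1)")
        if self.n_per_group < 2:
            raise ParameterError("need n >= 2 per group")
        if self.sides not in ("two-sided", "one-sided"):
            raise ParameterError(f"sides must be 'two-sided' or 'one-sided', got {self.sides!r}")


def power_two_sample_t(
    n_per_group: int, d: float, alpha: float = 0.05, sides: str = "two-sided"
) -> float:
    """Power of the equal-n two-sample t test at standardized effect size d.

    Rejection probability under a noncentral t with df = 2n - 2 and
    noncentrality d * sqrt(n/2).
    """
    PowerSpec(n_per_group, alpha, max(alpha + 1e-12, 0.5), sides).validate()
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    if sides == "two-sided":
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
        upper = stats.nct.sf(tc, df, ncp)
        lower = stats.nct.cdf(-tc, df, ncp)  # numerically 0 (can be NaN) at large ncp
        return float(np.nan_to_num(upper, nan=1.0) + np.nan_to_num(lower, nan=0.0))
    tc = stats.t.ppf(1.0 - alpha, df)
    return float(np.nan_to_num(stats.nct.sf(tc, df, ncp), nan=1.0))


def effect_size_from_power(
    n_per_group: int,
    alpha: float = 0.05,
    power: float = 0.8,
    sides: str = "two-sided",
) -> float:
    """The standardized effect size d achieving the target power.

    Solves ``power_two_sample_t(n, d) = power`` by monotone root finding;
    inverse-consistent with :func:`power_two_sample_t` to ~1e-6.
    """
    PowerSpec(n_per_group, alpha, power, sides).validate()
    lo, hi = 1e-9, 1.0
    while power_two_sample_t(n_per_group, hi, alpha, sides) < power:
        hi *= 2.0
        if hi > 100.0:
            raise ParameterError("target power unattainable for this design")
    return float(
        optimize.brentq(
            lambda d: power_two_sample_t(n_per_group, d, alpha, sides) - power,
            lo, hi, xtol=1e-10,
        )
    )


# --------------------------------------------------------------------------
# descriptives and frequency tables
# --------------------------------------------------------------------------

def descriptive_summary(x) -> dict:
    """Median, min, max and IQR (linear-interpolation quantiles)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("empty sample")
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
        "iqr": float(q3 - q1),
    }


def stage_frequency_table(
    records: Union[pd.DataFrame, Sequence[ScoreRecord]],
    variable: str,
    normalize: bool = False,
) -> pd.DataFrame:
    """Counts of each ordinal stage per (group, time) cell.

    Rows are stages, columns a (group, time_days) MultiIndex; column sums
    equal cell sample sizes (counts conserve total n).  With ``normalize``
    each column is divided by its cell total, as plotted in severity
    heat maps.  Non-integer-valued records raise: the table is defined for
    ordinal variables only.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    sub = df[df["variable"] == variable]
    if sub.empty:
        raise ParameterError(f"no records for variable {variable!r}")
    vals = sub["value"].to_numpy(float)
    if not np.allclose(vals, np.round(vals)):
        raise ParameterError(f"variable {variable!r} is not ordinal (non-integer values)")
    sub = sub.assign(stage=vals.astype(int))
    table = pd.crosstab(sub["stage"], [sub["group"], sub["time_days"]])
    table.columns.names = ["group", "time_days"]
    if normalize:
        table = table / table.sum(axis=0)
    return table
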