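"""Method-agreement statistics for multi-method MRD1 cohorts.

Implements the full battery a clinical method-comparison study runs on
an eyes x methods measurement table: descriptives with t-based
confidence intervals, one-way ANOVA across methods, Scheffe post hoc
pairwise comparisons, Pearson correlations, Bland-Altman limits of
agreement and simple linear regression — plus the cohort exclusion
filter applied upstream of all of them.

Every moment-based quantity (ANOVA, Scheffe, Bland-Altman mean
difference) has a variant that consumes only per-group summary moments
``(n, mean, sd)``. That matters because published comparison studies
print exactly those moments: the whole ANOVA decomposition, the Scheffe
table and the pairwise mean differences are recoverable from a printed
descriptives table without any raw per-eye data. The raw-data and
moments variants agree to floating-point accuracy (a tested invariant).

Conventions: eyes are treated as independent observations and methods
as independent groups (matching standard practice in the published
comparisons, which analyze eyes rather than patients and run an
unpaired ANOVA on paired columns); all p-values are two-tailed; the
Bland-Altman difference for a pair (A, B) is A - B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CohortError
from .synthetic import METHOD_COLUMNS, METHODS

DEFAULT_LOA_MULTIPLIER = 1.96


# ---------------------------------------------------------------------------
# descriptives


@dataclass
class Descriptives:
    n: int
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float


def se_from_moments(n: int, sd: float) -> float:
    """Standard error of the mean from n and the sample SD."""
    if n < 2:
        raise ValueError("standard error undefined for n < 2")
    return sd / np.sqrt(n)


def ci_from_moments(n: int, mean: float, sd: float, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for the mean from summary moments."""
    se = se_from_moments(n, sd)
    t = sps.t.ppf(0.5 + level / 2.0, n - 1)
    return mean - t * se, mean + t * se


def describe(values: Sequence[float], level: float = 0.95) -> Descriptives:
    """Descriptive row: n, mean, SD, SE and t-based CI, min, max."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("descriptives require at least 2 finite values")
    n, mean, sd = int(x.size), float(x.mean()), float(x.std(ddof=1))
    lo, hi = ci_from_moments(n, mean, sd, level)
    return Descriptives(n, mean, sd, float(se_from_moments(n, sd)), float(lo), float(hi),
                        float(x.min()), float(x.max()))


# ---------------------------------------------------------------------------
# one-way ANOVA


@dataclass
class AnovaTable:
    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    f: float
    p: float
    ss_total: float
    df_total: int
    grand_mean: float
    pooled_sd: float
    n_total: int
    infinite_f: bool = False


def anova_from_moments(groups: Sequence[tuple[int, float, float]]) -> AnovaTable:
    """One-way ANOVA from per-group ``(n, mean, sd)`` moments.

    SS_between = sum n_i (mean_i - grand_mean)^2 and
    SS_within = sum (n_i - 1) sd_i^2; the decomposition is exact, so the
    result is identical to running on raw data with those moments. The
    pooled Total row (grand mean, total SD) is included. Zero
    within-group variance with unequal means is flagged
    (``infinite_f``) rather than raised.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    n_total = int(ns.sum())
    grand = float(np.sum(ns * means) / n_total)
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(np.sum((ns - 1) * sds**2))
    df_b, df_w = len(groups) - 1, n_total - len(groups)
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    infinite = ms_w == 0.0 and ss_b > 0.0
    if infinite:
        f, p = np.inf, 0.0
    elif ms_w == 0.0:
        f, p = 0.0, 1.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    ss_t = ss_b + ss_w
    pooled_sd = float(np.sqrt(ss_t / (n_total - 1)))
    return AnovaTable(ss_b, df_b, ms_b, ss_w, df_w, ms_w, float(f), float(p),
                      ss_t, n_total - 1, grand, pooled_sd, n_total, infinite)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """One-way ANOVA on raw per-group samples (via the exact moments)."""
    moments = []
    for g in groups:
        x = np.asarray(g, dtype=float)
        if x.size < 2:
            raise ValueError("each group needs n >= 2")
        moments.append((int(x.size), float(x.mean()), float(x.std(ddof=1))))
    return anova_from_moments(moments)


# ---------------------------------------------------------------------------
# Scheffe post hoc


@dataclass
class ScheffePair:
    method_i: str
    method_j: str
    diff: float
    se: float
    p_adj: float
    ci_low: float
    ci_high: float


def scheffe_posthoc(
    moments: dict[str, tuple[int, float, float]],
    ms_within: float,
    df_within: int,
    level: float = 0.95,
) -> list[ScheffePair]:
    """Scheffe pairwise comparisons from group moments and the ANOVA MSE.

    For pair (i, j): diff = mean_i - mean_j,
    SE = sqrt(MS_within (1/n_i + 1/n_j)), adjusted
    p = P(F_{k-1, df_w} >= (diff/SE)^2 / (k-1)), and the simultaneous CI
    is diff +/- sqrt((k-1) F_crit) SE. Both orderings of each pair are
    returned, mirroring the symmetric layout of standard software output.
    """
    if df_within <= 0:
        raise ValueError("df_within must be positive")
    k = len(moments)
    if k < 2:
        raise ValueError("need at least 2 groups")
    f_crit = sps.f.ppf(level, k - 1, df_within)
    half_width_factor = np.sqrt((k - 1) * f_crit)
    out = []
    for (mi, (ni, meani, _)), (mj, (nj, meanj, _)) in combinations(moments.items(), 2):
        diff = meani - meanj
        se = float(np.sqrt(ms_within * (1.0 / ni + 1.0 / nj)))
        if se == 0.0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(sps.f.sf((diff / se) ** 2 / (k - 1), k - 1, df_within))
        hw = half_width_factor * se
        out.append(ScheffePair(mi, mj, float(diff), se, p, float(diff - hw), float(diff + hw)))
        out.append(ScheffePair(mj, mi, float(-diff), se, p, float(-diff - hw), float(-diff + hw)))
    return out


# ---------------------------------------------------------------------------
# correlation / agreement / regression


def pearson_matrix(table: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-tailed p-values.

    Returns ``(r, p)`` DataFrames (symmetric, unit diagonal / zero
    diagonal). A zero-variance column yields NaN entries rather than an
    exception.
    """
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pair = table[[columns[a], columns[b]]].dropna()
            if len(pair) < 3:
                raise ValueError(f"need >= 3 complete rows for {columns[a]} vs {columns[b]}")
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                continue
            res = sps.pearsonr(x, y)
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    return (pd.DataFrame(r, index=columns, columns=columns),
            pd.DataFrame(p, index=columns, columns=columns))


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    delta_loa: float
    n: int
    multiplier: float = DEFAULT_LOA_MULTIPLIER


def bland_altman(
    x: Sequence[float], y: Sequence[float], multiplier: float = DEFAULT_LOA_MULTIPLIER
) -> BlandAltman:
    """Bland-Altman agreement of paired measurements.

    Differences d = x - y; limits of agreement are
    mean(d) +/- multiplier * sd(d) and delta-LOA is their width
    (upper minus lower = 2 * multiplier * sd).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_d, sd_d = float(d.mean()), float(d.std(ddof=1))
    lo, hi = mean_d - multiplier * sd_d, mean_d + multiplier * sd_d
    return BlandAltman(mean_d, sd_d, float(lo), float(hi), float(hi - lo), int(x.size), multiplier)


def bland_altman_mean_diff_from_moments(mean_x: float, mean_y: float) -> float:
    """Bland-Altman mean difference from the two group means alone.

    mean(x - y) = mean(x) - mean(y) exactly, so the headline
    Bland-Altman number is recoverable from a printed descriptives table
    (the LOA are not: they need the SD of the paired differences).
    """
    return mean_x - mean_y


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y on x with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("var(x) = 0: regression undefined")
    res = sps.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2), int(x.size))


# ---------------------------------------------------------------------------
# cohort exclusion filter


EXCLUSION_RULES = {
    1: "missing manual rater replicates",
    2: "manual MRD1 <= 0",
    3: "indistinct pupil-iris boundary in the RGB image",
    4: "manual vs reference discrepancy above threshold",
    5: "machine measurement failure",
    6: "eyelid surgery within the washout window",
}


@dataclass
class ExclusionReport:
    counts: dict[int, int]
    retained_ids: list
    n_input: int

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def apply_exclusions(
    table: pd.DataFrame,
    reference_method: str = "rgb",
    max_discrepancy_mm: float = 1.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the six cohort exclusion rules, first match wins.

    Rules, in order: (1) any missing manual rater replicate (or missing
    manual value when no replicate columns exist); (2) manual MRD1 of
    zero or below; (3) the ``rgb_boundary_indistinct`` flag, or a
    missing RGB value; (4) |manual - reference| exceeding
    ``max_discrepancy_mm`` (default 1.0 mm), the reference being the RGB
    or IR image-analysis column; (5) a missing machine (DL) value or the
    ``machine_failed`` flag; (6) the ``recent_surgery`` flag. Each
    excluded row is counted once, under the first rule that fires.
    """
    if reference_method not in METHODS:
        raise CohortError(f"unknown reference method {reference_method!r}; expected one of {METHODS}")
    ref_col = METHOD_COLUMNS[reference_method]
    if ref_col not in table.columns:
        raise CohortError(f"reference column {ref_col!r} missing from table")
    rep_cols = [c for c in table.columns if c.startswith("mrd1_manual_r")]
    counts = {r: 0 for r in EXCLUSION_RULES}
    keep = []
    for idx, row in table.iterrows():
        rule = None
        if rep_cols:
            if any(pd.isna(row[c]) for c in rep_cols):
                rule = 1
        elif pd.isna(row.get("mrd1_manual")):
            rule = 1
        if rule is None and row["mrd1_manual"] <= 0:
            rule = 2
        if rule is None and (bool(row.get("rgb_boundary_indistinct", False)) or pd.isna(row.get("mrd1_rgb"))):
            rule = 3
        if rule is None:
            if pd.isna(row[ref_col]) or abs(row["mrd1_manual"] - row[ref_col]) > max_discrepancy_mm:
                rule = 4
        if rule is None and (bool(row.get("machine_failed", False)) or pd.isna(row.get("mrd1_dl"))):
            rule = 5
        if rule is None and bool(row.get("recent_surgery", False)):
            rule = 6
        if rule is None:
            keep.append(idx)
        else:
            counts[rule] += 1
    retained = table.loc[keep].copy()
    return retained, ExclusionReport(counts=counts, retained_ids=list(keep), n_input=len(table))


# ---------------------------------------------------------------------------
# composed report


@dataclass
class AgreementReport:
    descriptives: dict[str, Descriptives]
    total: Descriptives
    anova: AnovaTable
    scheffe: list[ScheffePair]
    pearson_r: pd.DataFrame
    pearson_p: pd.DataFrame
    bland_altman: dict[tuple[str, str], BlandAltman]
    regressions: dict[tuple[str, str], LinearFit]
    n_eyes: int
    methods: tuple[str, ...] = METHODS
    significance_threshold: float = 0.05

    def to_dict(self) -> dict:
        return {
            "n_eyes": self.n_eyes,
            "methods": list(self.methods),
            "descriptives": {m: vars(d) for m, d in self.descriptives.items()},
            "total": vars(self.total),
            "anova": vars(self.anova),
            "scheffe": [vars(s) for s in self.scheffe],
            "pearson_r": self.pearson_r.to_dict(),
            "pearson_p": self.pearson_p.to_dict(),
            "bland_altman": {f"{a}-{b}": vars(v) for (a, b), v in self.bland_altman.items()},
            "regressions": {f"{a}-{b}": vars(v) for (a, b), v in self.regressions.items()},
        }


def agreement_report(
    table: pd.DataFrame,
    methods: Sequence[str] = METHODS,
    loa_multiplier: float = DEFAULT_LOA_MULTIPLIER,
) -> AgreementReport:
    """Full agreement battery on a retained cohort table.

    Rows with any missing method value are dropped (the exclusion filter
    normally runs first and leaves none). The report layout mirrors the
    standard published presentation: per-method descriptives plus a
    pooled Total row, the one-way ANOVA, the symmetric Scheffe table,
    the Pearson matrix, and per-pair Bland-Altman and OLS regression
    blocks. Row order of the input does not affect any number.
    """
    cols = [METHOD_COLUMNS[m] for m in methods]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise CohortError(f"cohort table lacks columns {missing}")
    data = table[cols].dropna()
    if len(data) < 2:
        raise CohortError("need at least 2 complete rows")
    desc = {m: describe(data[METHOD_COLUMNS[m]]) for m in methods}
    total = describe(np.concatenate([data[c].to_numpy() for c in cols]))
    anova = anova_from_moments([(d.n, d.mean, d.sd) for d in desc.values()])
    scheffe = scheffe_posthoc(
        {m: (d.n, d.mean, d.sd) for m, d in desc.items()}, anova.ms_within, anova.df_within
    )
    r, p = pearson_matrix(data, cols)
    r.index = r.columns = list(methods)
    p.index = p.columns = list(methods)
    ba = {}
    reg = {}
    for a, b in combinations(methods, 2):
        xa, xb = data[METHOD_COLUMNS[a]], data[METHOD_COLUMNS[b]]
        ba[(a, b)] = bland_altman(xa, xb, loa_multiplier)
        reg[(a, b)] = linear_fit(xa, xb)
    return AgreementReport(desc, total, anova, scheffe, r, p, ba, reg, n_eyes=len(data),
                           methods=tuple(methods))
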