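"""Pairwise-interaction statistics.

Covers the statistical surface of the interaction assays: collapsing
directed halo records to unordered-pair antagonism labels, logistic
regression of inhibition on distance with McFadden pseudo-R², intersection
of two fitted logistic curves, McNemar's paired test, Pearson correlation,
one-way ANOVA with Dunnett's T3 post hoc comparisons, and one-sided
one-sample t tests for facilitation counting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate due to perfect separation."""


# ---------------------------------------------------------------------------
# inhibition coding
# ---------------------------------------------------------------------------

def pair_inhibition(records: pd.DataFrame, n_strains: int | None = None) -> pd.DataFrame:
    """Collapse directed halo records to unordered-pair antagonism labels.

    A pair (A, B) is antagonistic at a resource level iff A inhibited B
    (x = 1) and/or B inhibited A (y = 1).  Self pairs are controls and are
    reported separately (column ``is_self``).  With ``n_strains`` given,
    the design is checked for completeness: every ordered strain pair must
    appear at every resource level.
    """
    required = {"focal", "target", "resource_level", "halo"}
    if not required.issubset(records.columns):
        raise ValueError(f"inhibition records need columns {sorted(required)}")
    if not records["halo"].isin((0, 1)).all():
        raise ValueError("halo must be binary 0/1")
    strains = sorted(set(records["focal"]) | set(records["target"]))
    levels = sorted(records["resource_level"].unique())
    if n_strains is not None and len(strains) != n_strains:
        raise ValueError(f"expected {n_strains} strains, found {len(strains)}")
    seen = set(zip(records["focal"], records["target"], records["resource_level"]))
    if n_strains is not None:
        missing = [
            (f, t, lv)
            for f in strains for t in strains for lv in levels
            if (f, t, lv) not in seen
        ]
        if missing:
            raise ValueError(f"missing assay cells, e.g. {missing[:3]}")
    df = records.copy()
    lo = np.minimum(df["focal"], df["target"])
    hi = np.maximum(df["focal"], df["target"])
    df["strain_i"], df["strain_j"] = lo, hi
    out = (
        df.groupby(["resource_level", "strain_i", "strain_j"], sort=True)["halo"]
        .max()
        .rename("antagonistic")
        .reset_index()
    )
    out["is_self"] = out["strain_i"] == out["strain_j"]
    return out[["strain_i", "strain_j", "resource_level", "antagonistic", "is_self"]]


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmFit:
    """Binomial-GLM (logit) fit of a binary outcome on one predictor."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    llf: float
    llnull: float
    pseudo_r2: float  # McFadden: 1 - llf/llnull
    p_intercept: float
    p_slope: float
    n: int
    x_range: tuple[float, float]

    def predict(self, x: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_inhibition_glm(labels, distance) -> GlmFit:
    """Logistic regression of pair antagonism on pair distance.

    Maximum likelihood via iteratively reweighted least squares; reports
    Wald p-values and McFadden pseudo-R².  Raises ``ValueError`` for a
    constant predictor and ``SeparationError`` when the data are perfectly
    separated (the MLE diverges).
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(distance, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("labels and distances must be 1-d and equal length")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values in labels or distances")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    if np.ptp(x) == 0.0:
        raise ValueError(
            "constant predictor: all pair distances identical, slope unidentifiable"
        )
    if y.min() == y.max():
        raise SeparationError("all labels identical; logistic MLE undefined")
    exog = sm.add_constant(x)
    model = sm.Logit(y, exog)
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises on detected separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    fitted = res.predict(exog)
    if np.max(np.abs(fitted - y)) < 1e-8:
        raise SeparationError("perfect separation: fitted probabilities are 0/1")
    return GlmFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        llf=float(res.llf),
        llnull=float(res.llnull),
        pseudo_r2=float(1.0 - res.llf / res.llnull),
        p_intercept=float(res.pvalues[0]),
        p_slope=float(res.pvalues[1]),
        n=int(y.size),
        x_range=(float(x.min()), float(x.max())),
    )


def logistic_curve_intersection(fit_high: GlmFit, fit_low: GlmFit) -> tuple[float, bool]:
    """Distance at which two fitted logistic curves cross.

    The curves share the link, so they intersect where the linear
    predictors agree: x* = (b0_low - b0_high) / (b1_high - b1_low).
    Returns (x*, in_range) where ``in_range`` says whether x* falls inside
    the union of the observed distance ranges.  Raises when the slopes are
    equal (no crossing, or identical curves).
    """
    denom = fit_high.slope - fit_low.slope
    if denom == 0.0:
        raise ValueError("slopes are equal: curves do not cross at a unique point")
    x_star = (fit_low.intercept - fit_high.intercept) / denom
    lo = min(fit_high.x_range[0], fit_low.x_range[0])
    hi = max(fit_high.x_range[1], fit_low.x_range[1])
    return float(x_star), bool(lo <= x_star <= hi)


# ---------------------------------------------------------------------------
# paired and correlation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McNemarResult:
    chi2: float
    df: int
    p_one_sided: float
    b: int  # antagonistic at high only
    c: int  # antagonistic at low only
    corrected: bool


def mcnemar_paired(labels_high, labels_low, correction: bool = True) -> McNemarResult:
    """McNemar's test on paired binary labels (same pairs at two levels).

    chi2 = (|b - c| - k)^2 / (b + c) over the discordant counts, with
    continuity correction k = 1 by default (k = 0 available); df = 1.  The
    one-sided p is half the chi-square(1) upper tail.  Undefined (flagged
    by raising) when there are no discordant pairs.
    """
    h = np.asarray(labels_high, dtype=int)
    l = np.asarray(labels_low, dtype=int)
    if h.shape != l.shape or h.ndim != 1:
        raise ValueError("paired label vectors must be 1-d and equal length")
    b = int(np.sum((h == 1) & (l == 0)))
    c = int(np.sum((h == 0) & (l == 1)))
    if b + c == 0:
        raise ValueError("no discordant pairs: McNemar's test undefined")
    kappa = 1.0 if correction else 0.0
    chi2 = (max(abs(b - c) - kappa, 0.0)) ** 2 / (b + c)
    p = 0.5 * sps.chi2.sf(chi2, df=1)
    return McNemarResult(float(chi2), 1, float(p), b, c, correction)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p_two_sided: float
    n: int


def pearson_corr(x, y) -> PearsonResult:
    """Pearson product-moment correlation with pairwise NaN exclusion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least three complete observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return PearsonResult(
        r=float(res.statistic),
        r_squared=float(res.statistic**2),
        p_two_sided=float(res.pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# ANOVA + Dunnett T3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaT3Result:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    comparisons: pd.DataFrame = field(repr=False)


def anova_dunnett_t3(groups: dict[str, np.ndarray]) -> AnovaT3Result:
    """One-way ANOVA with Dunnett's T3 pairwise post hoc comparisons.

    The omnibus F uses the classical between/within decomposition with
    (k - 1, N - k) degrees of freedom.  T3 comparisons do not assume equal
    variances: each pair gets a Welch-type t statistic with
    Welch-Satterthwaite degrees of freedom, adjusted over the m = k(k-1)/2
    comparisons via the studentized-maximum-modulus bound
    p_adj = 1 - (2 F_t(|t|) - 1)^m.  At k = 2 this reduces to the Welch
    two-sample t test.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than two observations")
    f_stat, p = sps.f_oneway(*arrays.values())
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())

    m = k * (k - 1) // 2
    rows = []
    for (na, a), (nb, b) in itertools.combinations(arrays.items(), 2):
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se = math.sqrt(va + vb)
        if se == 0.0:
            raise ValueError(f"groups {na!r} and {nb!r} have zero pooled variance")
        t = (a.mean() - b.mean()) / se
        df_w = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        p_raw = 2.0 * sps.t.sf(abs(t), df_w)
        p_adj = 1.0 - (1.0 - p_raw) ** m
        rows.append((na, nb, a.mean() - b.mean(), t, df_w, p_raw, min(p_adj, 1.0)))
    comparisons = pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "mean_diff", "t", "df", "p_welch", "p_t3"],
    )
    return AnovaT3Result(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
        comparisons=comparisons,
    )


def one_sample_greater(values, mu0: float = 0.0) -> float:
    """One-sided one-sample t test p-value for mean > mu0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(v) == 0.0:
        if v[0] == mu0:
            raise ValueError("zero variance with mean equal to mu0: undefined")
        return 0.0 if v[0] > mu0 else 1.0
    return float(sps.ttest_1samp(v, mu0, alternative="greater").pvalue)
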