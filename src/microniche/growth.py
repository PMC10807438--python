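"""Logistic growth fitting and spent-media (supernatant) interaction ratios.

Growth curves are fitted with the three-parameter logistic model

    N(t) = K / (1 + ((K - N0) / N0) exp(-r t))

by nonlinear least squares.  Spent-media cases compare a strain's OD after
growth in a donor's cell-free supernatant with its OD in fresh medium; the
case statistic is log10(mean OD_spent / mean OD_fresh) and the case class
(positive / negative / neutral) comes from one-sided t tests on the
per-replicate log ratios at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import logistic_curve
from .stats import one_sample_greater


@dataclass(frozen=True)
class GrowthFit:
    K: float
    r: float
    N0: float
    residual_sd: float
    converged: bool


def fit_growth(time_h, od) -> GrowthFit:
    """Least-squares logistic fit to an OD time series.

    Initialisation: K from the series maximum, N0 from the first positive
    reading, r from the log-slope of the early exponential phase.  Raises
    for series that cannot carry a growth signal (all zero, or overall
    decreasing); non-convergence is returned flagged, never silently.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and OD must be 1-d and equal length")
    if t.size < 5:
        raise ValueError("need at least five time points")
    if np.all(y <= 0):
        raise ValueError("all-zero (or negative) OD series")
    if y[-1] < y[0] and np.polyfit(t, y, 1)[0] < 0:
        raise ValueError("monotone-decreasing OD series is not logistic growth")

    k0 = float(y.max())
    positive = y[y > 0]
    n0 = float(positive[0]) if positive.size else k0 / 100.0
    n0 = min(n0, 0.9 * k0)
    # early-phase log slope, using the first half of the dynamic range
    early = y < (n0 + 0.5 * (k0 - n0))
    if early.sum() >= 2 and np.all(y[early] > 0):
        slope = np.polyfit(t[early], np.log(y[early]), 1)[0]
        r0 = float(max(slope, 1e-3))
    else:
        r0 = 0.1
    try:
        popt, _ = curve_fit(
            logistic_curve, t, y, p0=(k0, r0, n0),
            bounds=((1e-12, 0.0, 1e-12), (np.inf, np.inf, np.inf)),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt, converged = (k0, r0, n0), False
    resid = y - logistic_curve(t, *popt)
    dof = max(t.size - 3, 1)
    return GrowthFit(
        K=float(popt[0]), r=float(popt[1]), N0=float(popt[2]),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        converged=converged,
    )


def fit_growth_table(series: pd.DataFrame, by=("strain", "resource_level", "replicate")) -> pd.DataFrame:
    """Fit every (strain, resource level, replicate) series in a long table
    with columns time_h and od; returns one row of fit parameters per group."""
    by = [c for c in by if c in series.columns]
    rows = []
    for key, grp in series.groupby(by) if by else [((), series)]:
        key = key if isinstance(key, tuple) else (key,)
        fit = fit_growth(grp["time_h"].to_numpy(), grp["od"].to_numpy())
        rows.append(dict(zip(by, key)) | {
            "K": fit.K, "r": fit.r, "N0": fit.N0,
            "residual_sd": fit.residual_sd, "converged": fit.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# supernatant assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SupernatantCase:
    grower_id: str
    donor_id: str
    resource_level: str
    od_spent: tuple
    od_fresh: tuple
    log_ratio: float  # log10(mean spent / mean fresh)
    replicate_log_ratios: tuple
    classification: str  # positive / negative / neutral


def spent_ratio(
    grower_id: str,
    donor_id: str,
    resource_level: str,
    od_spent,
    od_fresh,
    alpha: float = 0.05,
) -> SupernatantCase:
    """Spent/fresh growth ratio and interaction class for one case.

    The displayed statistic is the log10 ratio of replicate-mean ODs;
    significance is tested on per-replicate log ratios (replicate i spent
    paired with replicate i fresh): positive if greater-than-zero p <
    alpha, negative if the mirrored test rejects, else neutral.
    """
    spent = np.asarray(od_spent, dtype=float)
    fresh = np.asarray(od_fresh, dtype=float)
    if spent.shape != fresh.shape or spent.ndim != 1:
        raise ValueError("spent and fresh OD vectors must be 1-d and equal length")
    if (spent <= 0).any() or (fresh <= 0).any():
        raise ValueError("ODs must be positive to form ratios")
    rep_log = np.log10(spent / fresh)
    log_ratio = float(np.log10(spent.mean() / fresh.mean()))
    if np.ptp(rep_log) == 0.0:
        # exact replicates: sign decides, zero is neutral
        cls = ("positive" if rep_log[0] > 0
               else "negative" if rep_log[0] < 0 else "neutral")
    else:
        if one_sample_greater(rep_log) < alpha:
            cls = "positive"
        elif one_sample_greater(-rep_log) < alpha:
            cls = "negative"
        else:
            cls = "neutral"
    return SupernatantCase(
        grower_id=grower_id,
        donor_id=donor_id,
        resource_level=resource_level,
        od_spent=tuple(spent),
        od_fresh=tuple(fresh),
        log_ratio=log_ratio,
        replicate_log_ratios=tuple(rep_log),
        classification=cls,
    )


def spent_ratio_table(table: pd.DataFrame, alpha: float = 0.05) -> list[SupernatantCase]:
    """Build SupernatantCase objects from a long OD table with columns
    grower, donor, resource_level, replicate, od_spent, od_fresh."""
    required = {"grower", "donor", "resource_level", "replicate", "od_spent", "od_fresh"}
    if not required.issubset(table.columns):
        raise ValueError(f"supernatant table needs columns {sorted(required)}")
    cases = []
    for (grower, donor, level), grp in table.groupby(
        ["grower", "donor", "resource_level"], sort=True
    ):
        grp = grp.sort_values("replicate")
        cases.append(
            spent_ratio(grower, donor, level,
                        grp["od_spent"].to_numpy(), grp["od_fresh"].to_numpy(),
                        alpha=alpha)
        )
    return cases


def facilitation_summary(cases: list[SupernatantCase], alpha: float = 0.05) -> dict:
    """Class counts per resource level and high-minus-low contrasts.

    For every (grower, donor) present at both levels the contrast is
    delta = log_ratio_high - log_ratio_low, with per-replicate deltas
    (replicate-paired) tested one-sided against zero; the summary reports
    the count and fraction of cases with delta significantly above zero
    (relative facilitation under high resource availability).
    """
    if not cases:
        raise ValueError("no supernatant cases")
    by_level: dict[str, dict[tuple, SupernatantCase]] = {}
    for c in cases:
        by_level.setdefault(c.resource_level, {})[(c.grower_id, c.donor_id)] = c
    counts = {
        level: {
            "positive": sum(c.classification == "positive" for c in d.values()),
            "negative": sum(c.classification == "negative" for c in d.values()),
            "neutral": sum(c.classification == "neutral" for c in d.values()),
            "n": len(d),
        }
        for level, d in by_level.items()
    }
    out = {"class_counts": counts}
    if {"high", "low"} <= set(by_level):
        high, low = by_level["high"], by_level["low"]
        if set(high) != set(low):
            raise ValueError("high and low levels cover different cases")
        deltas, n_sig = [], 0
        for key in sorted(high):
            h, l = high[key], low[key]
            deltas.append(h.log_ratio - l.log_ratio)
            rep_delta = np.subtract(h.replicate_log_ratios, l.replicate_log_ratios)
            if np.ptp(rep_delta) == 0.0:
                sig = rep_delta[0] > 0
            else:
                sig = one_sample_greater(rep_delta) < alpha
            n_sig += bool(sig)
        out["delta_high_minus_low"] = {
            "n_cases": len(deltas),
            "mean_delta": float(np.mean(deltas)),
            "n_delta_positive": int(sum(d > 0 for d in deltas)),
            "n_delta_significant": int(n_sig),
            "fraction_delta_significant": n_sig / len(deltas),
        }
    return out
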