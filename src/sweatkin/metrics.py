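"""Method-comparison statistics for estimated vs. measured blood urea.

RMSE, RMSPE, Pearson (and Spearman) correlation with Fisher-z confidence
intervals, Bland–Altman agreement, two-tailed Wilcoxon signed-rank tests and
GFR-stratified summaries — the standard toolkit for validating a surrogate
measurement against a reference assay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: GFR group boundaries (mL/min/1.73 m²); 5 and 8 belong to the mid group.
GFR_GROUPS = (("low", 0.0, 5.0), ("mid", 5.0, 8.0), ("high", 8.0, math.inf))


@dataclass
class MetricsReport:
    """Aggregate agreement metrics between estimates and measurements."""

    n: int
    rmse: float  # mmol/L
    rmspe: float  # %
    pearson_r: float
    pearson_ci: tuple[float, float]
    bias: float  # mmol/L, mean(est − meas)
    loa_half_width: float  # mmol/L, 1.96·SD of differences
    per_timepoint: dict[str, dict[str, float]] = field(default_factory=dict)
    stratified: list[dict[str, float]] = field(default_factory=list)
    excluded_missing_gfr: int = 0


def _paired(estimated, measured) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape:
        raise ValueError("estimated and measured must have equal length")
    if est.size == 0:
        raise ValueError("empty input")
    return est, meas


def rmse(estimated, measured) -> float:
    """Root mean square error, same units as the inputs."""
    est, meas = _paired(estimated, measured)
    return float(np.sqrt(np.mean((est - meas) ** 2)))


def rmspe(estimated, measured) -> float:
    """Root mean square percentage error (%), relative to *measured*."""
    est, meas = _paired(estimated, measured)
    if np.any(meas <= 0):
        raise ValueError("rmspe requires strictly positive measured values")
    return float(100.0 * np.sqrt(np.mean(((est - meas) / meas) ** 2)))


def pearson_with_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher-z confidence interval."""
    x, y = _paired(x, y)
    if x.size < 4:
        raise ValueError("need at least 4 pairs for a confidence interval")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=level)
    return float(res.statistic), float(ci.low), float(ci.high)


def spearman_with_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Spearman rank correlation with a Fisher-z interval on the rho scale."""
    x, y = _paired(x, y)
    if x.size < 4:
        raise ValueError("need at least 4 pairs for a confidence interval")
    rho = float(stats.spearmanr(x, y).statistic)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.06 / math.sqrt(x.size - 3)  # Fieller correction for ranks
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    # guard the degenerate |rho| = 1 case against tanh round-off
    return rho, float(min(lo, rho)), float(max(hi, rho))


def bland_altman(estimated, measured) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement ``bias ± 1.96·SD`` (sample SD, n−1).

    Returns ``(bias, loa_lo, loa_hi)``.
    """
    est, meas = _paired(estimated, measured)
    if est.size < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    diff = est - meas
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def wilcoxon_signed_rank(errors_a, errors_b) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired error samples.

    Zero differences are discarded; the exact null distribution is used for
    n ≤ 25 without ties, otherwise a normal approximation with tie
    correction.  All differences zero returns p = 1 with a warning.
    """
    a, b = _paired(errors_a, errors_b)
    diff = a - b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1")
        return 1.0
    if nonzero.size < 5:
        warnings.warn("fewer than 5 nonzero differences; p-value is unreliable")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    return float(res.pvalue)


def stratify_by_gfr(samples: pd.DataFrame, estimates_col: str = "C_blood_est",
                    measured_col: str = "blood_urea_mmol_per_L") -> tuple[list[dict], int]:
    """Per-GFR-group RMSE/RMSPE, split by timepoint.

    Group membership: low ``[0, 5)``, mid ``[5, 8]``, high ``(8, ∞)``.
    Samples without a GFR value are excluded; their count is returned.
    """
    if "gfr" not in samples.columns:
        raise ValueError("samples must carry a 'gfr' column")
    usable = samples.dropna(subset=["gfr", estimates_col, measured_col])
    excluded = len(samples) - len(usable)
    rows: list[dict] = []
    for name, lo, hi in GFR_GROUPS:
        if name == "mid":
            grp = usable[(usable.gfr >= lo) & (usable.gfr <= hi)]
        elif name == "low":
            grp = usable[usable.gfr < hi]
        else:
            grp = usable[usable.gfr > lo]
        entry: dict = {"group": name, "n": int(grp["sample_id"].nunique()
                                               if "sample_id" in grp else len(grp))}
        for tp in ("pre", "post"):
            sub = grp[grp.timepoint == tp] if "timepoint" in grp.columns else grp
            if len(sub):
                entry[f"{tp}_rmse"] = rmse(sub[estimates_col], sub[measured_col])
                entry[f"{tp}_rmspe"] = rmspe(sub[estimates_col], sub[measured_col])
            else:
                entry[f"{tp}_rmse"] = math.nan
                entry[f"{tp}_rmspe"] = math.nan
        rows.append(entry)
    return rows, excluded


def evaluate(samples: pd.DataFrame, estimates_col: str = "C_blood_est",
             measured_col: str = "blood_urea_mmol_per_L") -> MetricsReport:
    """Full agreement report between estimated and measured blood urea."""
    usable = samples.dropna(subset=[estimates_col, measured_col])
    est = usable[estimates_col].to_numpy(float)
    meas = usable[measured_col].to_numpy(float)
    r, lo, hi = pearson_with_ci(est, meas)
    bias, loa_lo, loa_hi = bland_altman(est, meas)
    per_tp: dict[str, dict[str, float]] = {}
    if "timepoint" in usable.columns:
        for tp, grp in usable.groupby("timepoint"):
            e = grp[estimates_col].to_numpy(float)
            m = grp[measured_col].to_numpy(float)
            entry = {"n": len(grp), "rmse": rmse(e, m), "rmspe": rmspe(e, m)}
            if len(grp) >= 2:
                b, l_lo, l_hi = bland_altman(e, m)
                entry.update(bias=b, loa_half_width=(l_hi - l_lo) / 2)
            per_tp[str(tp)] = entry
    strat: list[dict] = []
    excluded = 0
    if "gfr" in usable.columns and usable["gfr"].notna().any():
        strat, excluded = stratify_by_gfr(usable, estimates_col, measured_col)
    return MetricsReport(
        n=len(usable),
        rmse=rmse(est, meas),
        rmspe=rmspe(est, meas),
        pearson_r=r,
        pearson_ci=(lo, hi),
        bias=bias,
        loa_half_width=(loa_hi - loa_lo) / 2,
        per_timepoint=per_tp,
        stratified=strat,
        excluded_missing_gfr=excluded,
    )
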