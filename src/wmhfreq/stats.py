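"""Inferential statistics for the lesion/microstructure analysis.

Three procedures:

* paired t-test — per-subject mean FA inside WMH vs inside NAWM;
* simple linear regression — WMH volume (cm^3) regressed on mean FA within
  WMH (slope B in cm^3 per unit FA; the reverse direction is available);
* one-way repeated-measures ANOVA on the within-subject frequency-bin factor
  with a Satterthwaite-type (Box / Greenhouse-Geisser) sphericity correction:
  the epsilon estimated from the sample covariance of the bin columns
  multiplies both numerator and denominator degrees of freedom, yielding the
  fractional df characteristic of unequal variances across bins. With two
  bins the corrected F is exactly the squared paired t statistic and
  epsilon = 1. A Welch one-way ANOVA treating bins as independent groups is
  provided as a sensitivity variant.

All tests are two-sided with 95% confidence intervals and no covariate
adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult", "RegressionResult", "WsAnovaResult", "ZeroVarianceError",
    "paired_t_test", "simple_linear_regression", "box_epsilon", "ws_anova",
    "welch_anova", "analysis_report", "write_report",
]


class ZeroVarianceError(ValueError):
    """The requested statistic is undefined because all variation is zero."""


@dataclass
class PairedTestResult:
    mean_diff: float
    ci95: tuple
    t_stat: float
    df: int
    p_value: float
    n: int


@dataclass
class RegressionResult:
    slope_B: float
    ci95: tuple
    intercept: float
    p_value: float
    n: int


@dataclass
class WsAnovaResult:
    f_stat: float
    df1_corrected: float
    df2_corrected: float
    epsilon: float
    p_value: float
    variance_explained: float
    n_subjects: int
    n_bins: int


def _check_finite(name, arr):
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired t-test on d = x - y with a 95% CI for the mean."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    _check_finite("x", x)
    _check_finite("y", y)
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        if mean == 0:
            return PairedTestResult(0.0, (0.0, 0.0), 0.0, df, 1.0, n)
        t = float(np.sign(mean)) * float("inf")
        return PairedTestResult(mean, (mean, mean), t, df, 0.0, n)
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2 * sps.t.sf(abs(t), df))
    half = float(sps.t.ppf(0.975, df) * se)
    return PairedTestResult(mean, (mean - half, mean + half), float(t), df, p, n)


def simple_linear_regression(predictor, response) -> RegressionResult:
    """OLS slope/intercept with two-sided slope p-value and t-based 95% CI."""
    x = np.asarray(predictor, float).ravel()
    y = np.asarray(response, float).ravel()
    if x.shape != y.shape:
        raise ValueError("predictor and response must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    _check_finite("predictor", x)
    _check_finite("response", y)
    if np.ptp(x) == 0:
        raise ZeroVarianceError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    half = float(sps.t.ppf(0.975, n - 2) * res.stderr)
    return RegressionResult(
        slope_B=float(res.slope),
        ci95=(float(res.slope) - half, float(res.slope) + half),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=n,
    )


def box_epsilon(values: np.ndarray) -> float:
    """Box (Greenhouse-Geisser-type) sphericity epsilon from bin covariance.

    epsilon = (tr C)^2 / ((k-1) sum C_ij^2) with C the double-centered sample
    covariance matrix of the k within-subject columns. Bounded in
    [1/(k-1), 1]; equals 1 under compound symmetry.
    """
    Y = np.asarray(values, float)
    n, k = Y.shape
    S = np.cov(Y, rowvar=False)
    row = S.mean(axis=0, keepdims=True)
    C = S - row - row.T + S.mean()
    denom = (k - 1) * np.sum(C ** 2)
    if denom <= 0:
        return 1.0
    eps = float(np.trace(C) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def ws_anova(values, variant: str = "repeated") -> WsAnovaResult:
    """Unequal-variance ANOVA across within-subject bins.

    ``values`` is (n_subjects, n_bins) with no missing entries. The default
    ``repeated`` variant is the repeated-measures decomposition with the
    epsilon correction applied to both df; ``independent`` runs a Welch
    one-way ANOVA treating the columns as independent groups (sensitivity
    check; epsilon is reported as NaN there).
    """
    Y = np.asarray(values, float)
    if isinstance(values, pd.DataFrame):
        Y = values.to_numpy(dtype=float)
    if Y.ndim != 2:
        raise ValueError("values must be a 2-D (subjects x bins) array")
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least 2 bins")
    if n < k:
        raise ValueError(f"fewer subjects ({n}) than bins ({k})")
    _check_finite("values", Y)
    if variant == "independent":
        return welch_anova(Y)
    if variant != "repeated":
        raise ValueError(f"unknown variant {variant!r}")

    grand = Y.mean()
    col = Y.mean(axis=0)
    row = Y.mean(axis=1)
    ss_bins = n * np.sum((col - grand) ** 2)
    resid = Y - row[:, None] - col[None, :] + grand
    ss_error = np.sum(resid ** 2)
    if ss_bins + ss_error <= 0:
        raise ZeroVarianceError("zero within-subject variance: F undefined")
    if ss_error == 0:
        raise ZeroVarianceError("zero residual variance: F undefined")
    ms_bins = ss_bins / (k - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    f = ms_bins / ms_error
    eps = box_epsilon(Y)
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    p = float(sps.f.sf(f, df1, df2))
    return WsAnovaResult(
        f_stat=float(f), df1_corrected=float(df1), df2_corrected=float(df2),
        epsilon=float(eps), p_value=p,
        variance_explained=float(ss_bins / (ss_bins + ss_error)),
        n_subjects=n, n_bins=k)


def welch_anova(values) -> WsAnovaResult:
    """Welch's heteroscedastic one-way ANOVA on independent columns."""
    Y = np.asarray(values, float)
    n, k = Y.shape
    m = Y.mean(axis=0)
    v = Y.var(axis=0, ddof=1)
    if np.any(v == 0):
        raise ZeroVarianceError("a group has zero variance")
    w = n / v
    wsum = w.sum()
    mw = np.sum(w * m) / wsum
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / wsum) ** 2 / (n - 1))
    b = 1 + 2 * (k - 2) / (k ** 2 - 1) * lam
    f = a / b
    df1 = k - 1.0
    df2 = (k ** 2 - 1) / (3 * lam)
    p = float(sps.f.sf(f, df1, df2))
    grand = Y.mean()
    ss_b = n * np.sum((m - grand) ** 2)
    ss_w = np.sum((Y - m) ** 2)
    return WsAnovaResult(
        f_stat=float(f), df1_corrected=df1, df2_corrected=float(df2),
        epsilon=float("nan"), p_value=p,
        variance_explained=float(ss_b / (ss_b + ss_w)),
        n_subjects=n, n_bins=k)


def analysis_report(lesion_stats: pd.DataFrame, bin_matrix: pd.DataFrame,
                    ws_variant: str = "repeated",
                    regression_direction: str = "volume_on_fa") -> dict:
    """Run the three inferential procedures and assemble a results record.

    ``lesion_stats`` needs columns wmh_volume_cm3, mean_fa_wmh, mean_fa_nawm
    (one row per older subject); subjects with an undefined (NaN) WMH mean FA
    — i.e. no segmented lesion voxels — are excluded from the two per-subject
    tests and their count is recorded. ``bin_matrix`` is the young-subject by
    frequency-bin normative-FA table.
    """
    df = lesion_stats
    ok = df[["mean_fa_wmh", "mean_fa_nawm"]].notna().all(axis=1)
    used = df[ok]
    n_dropped = int((~ok).sum())

    paired = paired_t_test(used["mean_fa_wmh"], used["mean_fa_nawm"])
    if regression_direction == "volume_on_fa":
        reg = simple_linear_regression(used["mean_fa_wmh"], used["wmh_volume_cm3"])
    elif regression_direction == "fa_on_volume":
        reg = simple_linear_regression(used["wmh_volume_cm3"], used["mean_fa_wmh"])
    else:
        raise ValueError(f"unknown regression_direction {regression_direction!r}")
    anova = ws_anova(bin_matrix, variant=ws_variant)

    return {
        "paired_t_fa_wmh_vs_nawm": asdict(paired),
        "regression_wmh_volume_on_fa": {**asdict(reg),
                                        "direction": regression_direction},
        "ws_anova_normative_fa_by_bin": {**asdict(anova), "variant": ws_variant},
        "bin_means": {c: float(bin_matrix[c].mean()) for c in bin_matrix.columns},
        "bin_sds": {c: float(bin_matrix[c].std(ddof=1)) for c in bin_matrix.columns},
        "n_old_used": int(ok.sum()),
        "n_old_dropped_empty_wmh": n_dropped,
        "n_young": int(bin_matrix.shape[0]),
    }


def write_report(report: dict, json_path, text_path=None) -> None:
    """Write the machine-readable (JSON) and human-readable summaries.

    Output is deterministic: keys sorted, fixed float formatting, no
    timestamps, so identical inputs yield byte-identical files.
    """
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if text_path is None:
        return
    p = report["paired_t_fa_wmh_vs_nawm"]
    r = report["regression_wmh_volume_on_fa"]
    a = report["ws_anova_normative_fa_by_bin"]
    lines = [
        "WMH / normative-FA analysis",
        "===========================",
        "",
        f"Paired t (FA in WMH vs NAWM), n = {p['n']}:",
        f"  mean difference = {p['mean_diff']:.4f} "
        f"(95% CI {p['ci95'][0]:.4f}, {p['ci95'][1]:.4f}), "
        f"t({p['df']}) = {p['t_stat']:.3f}, p = {p['p_value']:.3g}",
        "",
        f"Regression ({r['direction']}), n = {r['n']}:",
        f"  B = {r['slope_B']:.3f} (95% CI {r['ci95'][0]:.3f}, {r['ci95'][1]:.3f}), "
        f"p = {r['p_value']:.3g}",
        "",
        f"Repeated-measures ANOVA over frequency bins "
        f"({a['n_subjects']} subjects x {a['n_bins']} bins):",
        f"  F({a['df1_corrected']:.2f}, {a['df2_corrected']:.1f}) = "
        f"{a['f_stat']:.2f}, epsilon = {a['epsilon']:.3f}, p = {a['p_value']:.3g}, "
        f"variance explained = {100 * a['variance_explained']:.1f}%",
        "",
        "Bin means (normative FA): " + ", ".join(
            f"{k}: {v:.3f}" for k, v in report["bin_means"].items()),
        "",
    ]
    with open(text_path, "w") as fh:
        fh.write("\n".join(lines))
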