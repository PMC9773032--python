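"""Discrimination, calibration, and reclassification metrics.

C-statistic = P(score_case > score_control) + 0.5 * P(tie), with variance
and paired model contrasts from the DeLong structural-components
estimator. Calibration-in-the-large and slope follow the logistic-refit
convention (ideals 0 and 1). NRI and IDI follow the standard
reclassification definitions with large-sample normal inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "c_statistic",
    "delong_test",
    "CalibrationResult",
    "calibration",
    "ReclassificationMeasure",
    "nri",
    "idi",
]

_Z95 = stats.norm.ppf(0.975)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, outcomes: np.ndarray):
    """AUC and structural components V10 (cases) / V01 (controls)."""
    outcomes = np.asarray(outcomes, dtype=bool)
    pos = np.asarray(scores, dtype=float)[outcomes]
    neg = np.asarray(scores, dtype=float)[~outcomes]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both cases and controls to compute a C-statistic")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def c_statistic(scores, outcomes) -> tuple[float, tuple[float, float]]:
    """C-statistic with a 95% DeLong CI, clipped to [0, 1]."""
    auc, v10, v01 = _delong_components(scores, outcomes)
    var = _var(v10, v01)
    se = np.sqrt(var)
    ci = (max(0.0, auc - _Z95 * se), min(1.0, auc + _Z95 * se))
    return float(auc), ci


def _var(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = np.var(v10, ddof=1) if len(v10) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(v01) > 1 else 0.0
    return s10 / len(v10) + s01 / len(v01)


def delong_test(scores_a, scores_b, outcomes) -> dict:
    """Paired DeLong contrast of two C-statistics on the same patients.

    Returns the two AUCs, their difference, z, and z^2 treated as a 1-df
    chi-squared statistic with a two-sided P. Identical score vectors give
    chi2 = 0 and P = 1.
    """
    auc_a, v10_a, v01_a = _delong_components(scores_a, outcomes)
    auc_b, v10_b, v01_b = _delong_components(scores_b, outcomes)
    m, n = len(v10_a), len(v01_a)
    var_a = _var(v10_a, v01_a)
    var_b = _var(v10_b, v01_b)
    cov = 0.0
    if m > 1:
        cov += np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
    if n > 1:
        cov += np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
    var_diff = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        z = 0.0
        chi2 = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var_diff)
        chi2 = z * z
        p = float(stats.chi2.sf(chi2, df=1))
    return {
        "c_a": float(auc_a),
        "c_b": float(auc_b),
        "difference": float(diff),
        "z": float(z),
        "chi2": float(chi2),
        "p": p,
    }


@dataclass
class CalibrationResult:
    """Logistic-refit calibration: intercept-given-offset and slope."""

    citl: float
    citl_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]

    def summary(self) -> str:
        return (
            f"calibration-in-the-large={self.citl:.3f} "
            f"(95% CI {self.citl_ci[0]:.3f} to {self.citl_ci[1]:.3f}); "
            f"slope={self.slope:.3f} "
            f"(95% CI {self.slope_ci[0]:.3f} to {self.slope_ci[1]:.3f})"
        )


def calibration(linear_predictor, outcomes) -> CalibrationResult:
    """Calibration-in-the-large and calibration slope on validation data.

    Slope: coefficient of the linear predictor in ``outcome ~ 1 + LP``.
    CITL: intercept of ``outcome ~ 1`` with LP as a fixed offset.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.ptp(lp) < 1e-12:
        raise ValueError("degenerate (constant) linear predictor")
    slope_fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    slope = slope_fit.params[1]
    slope_se = slope_fit.bse[1]
    citl_fit = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
    ).fit()
    citl = citl_fit.params[0]
    citl_se = citl_fit.bse[0]
    return CalibrationResult(
        citl=float(citl),
        citl_ci=(float(citl - _Z95 * citl_se), float(citl + _Z95 * citl_se)),
        slope=float(slope),
        slope_ci=(float(slope - _Z95 * slope_se), float(slope + _Z95 * slope_se)),
    )


@dataclass
class ReclassificationMeasure:
    """An NRI or IDI estimate with CI, z, and two-sided P."""

    estimate: float
    ci: tuple[float, float]
    z: float
    p: float

    def summary(self) -> str:
        return (
            f"{self.estimate:.4g} (95% CI {self.ci[0]:.4g} to {self.ci[1]:.4g}); "
            f"z={self.z:.2f}; P={self.p:.3g}"
        )


def _split_events(old, new, outcomes):
    old = np.asarray(old, dtype=float)
    new = np.asarray(new, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if old.shape != new.shape or old.shape != y.shape:
        raise ValueError("probability vectors and outcomes must align")
    if y.all() or not y.any():
        raise ValueError("need both events and non-events")
    return old, new, y


def _nri_half(up: np.ndarray, down: np.ndarray) -> tuple[float, float, int]:
    n = len(up)
    pu, pd_ = up.mean(), down.mean()
    est = pu - pd_
    var = (pu + pd_ - est**2) / n
    return est, var, n


def nri(old, new, outcomes, cutpoints=None) -> dict[str, ReclassificationMeasure]:
    """Net reclassification improvement, continuous and (optionally) categorical.

    Event NRI = P(up | event) - P(down | event); non-event NRI =
    P(down | non-event) - P(up | non-event); total = sum. ``continuous``
    counts any directional change of predicted risk; ``categorical``
    counts risk-category crossings over strictly increasing ``cutpoints``.
    """
    old, new, y = _split_events(old, new, outcomes)
    out: dict[str, ReclassificationMeasure] = {}

    def build(up, down):
        e_est, e_var, _ = _nri_half(up[y], down[y])
        ne_est, ne_var, _ = _nri_half(down[~y], up[~y])
        est = e_est + ne_est
        se = np.sqrt(e_var + ne_var)
        if se < 1e-16:
            z, p = 0.0, 1.0
        else:
            z = est / se
            p = float(2 * stats.norm.sf(abs(z)))
        return ReclassificationMeasure(
            float(est), (float(est - _Z95 * se), float(est + _Z95 * se)), float(z), p
        )

    out["continuous"] = build(new > old, new < old)
    if cutpoints is not None:
        cut = np.asarray(cutpoints, dtype=float)
        if cut.ndim != 1 or len(cut) == 0 or np.any(np.diff(cut) <= 0):
            raise ValueError("cutpoints must be a non-empty strictly increasing vector")
        cat_old = np.searchsorted(cut, old, side="left")
        cat_new = np.searchsorted(cut, new, side="left")
        out["categorical"] = build(cat_new > cat_old, cat_new < cat_old)
    return out


def idi(old, new, outcomes) -> ReclassificationMeasure:
    """Integrated discrimination improvement.

    IDI = mean(new - old | events) - mean(new - old | non-events); z from
    the two-independent-samples variance of the per-subject differences.
    """
    old, new, y = _split_events(old, new, outcomes)
    d_e = new[y] - old[y]
    d_ne = new[~y] - old[~y]
    est = d_e.mean() - d_ne.mean()
    var = 0.0
    if len(d_e) > 1:
        var += np.var(d_e, ddof=1) / len(d_e)
    if len(d_ne) > 1:
        var += np.var(d_ne, ddof=1) / len(d_ne)
    se = np.sqrt(var)
    if se < 1e-16:
        z, p = 0.0, 1.0
    else:
        z = est / se
        p = float(2 * stats.norm.sf(abs(z)))
    return ReclassificationMeasure(
        float(est), (float(est - _Z95 * se), float(est + _Z95 * se)), float(z), p
    )
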