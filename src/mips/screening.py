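"""Univariable comorbidity screening on matched case-control halves.

The screen reproduces a common claims-analysis recipe: (1) keep
comorbidities with prevalence >= 1% in the combined matched set, (2)
compute the univariable case/control odds ratio of each retained
comorbidity in a training half and a replication half, (3) keep those
Bonferroni-significant in *both* halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "OddsRatio",
    "odds_ratio_2x2",
    "univariable_or",
    "prevalence_filter",
    "drop_empty_patients",
    "FeatureScreen",
    "FeatureScreenResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OddsRatio:
    """Univariable odds ratio with Wald CI and two-sided P value.

    ``degenerate`` marks tables with a zero cell (Haldane-Anscombe +0.5
    applied) or a constant exposure column.
    """

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> OddsRatio:
    """OR = (a*d)/(b*c) for exposed-case a, exposed-control b,
    unexposed-case c, unexposed-control d.

    Wald CI/P on the log scale; any zero cell triggers the
    Haldane-Anscombe +0.5 correction on all four cells and sets the
    degenerate flag. A constant exposure (a+b == 0 or c+d == 0) or a
    constant outcome is degenerate with an undefined (NaN) estimate.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OddsRatio(np.nan, np.nan, np.nan, np.nan, degenerate=True)
    degenerate = min(a, b, c, d) == 0
    if degenerate:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    lo, hi = np.exp(log_or - 1.959963984540054 * se), np.exp(log_or + 1.959963984540054 * se)
    return OddsRatio(float(np.exp(log_or)), float(lo), float(hi), float(p), degenerate)


def univariable_or(cohort: Cohort, comorbidity: int) -> OddsRatio:
    """Case/control odds ratio of one comorbidity (0-based column index)."""
    x = cohort.X[:, comorbidity].astype(bool)
    y = cohort.is_case
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return odds_ratio_2x2(a, b, c, d)


def prevalence_filter(cohort: Cohort, threshold: float = 0.01) -> np.ndarray:
    """0-based indices of comorbidities with prevalence >= threshold.

    Strictly-below-threshold comorbidities are dropped; exact ties are
    retained.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    prev = cohort.X.mean(axis=0)
    return np.flatnonzero(prev >= threshold)


def drop_empty_patients(cohort: Cohort, selected: np.ndarray) -> Cohort:
    """Remove patients with none of the selected comorbidities.

    Logs the removed count. Raises if every patient would be removed.
    """
    selected = np.asarray(selected)
    if selected.size == 0:
        raise ValueError("selected comorbidity set is empty")
    keep = cohort.X[:, selected].sum(axis=1) > 0
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all patients removed: no one carries a selected comorbidity")
    if removed:
        logger.info("dropped %d patients with no selected comorbidity", removed)
    return cohort.subset(keep)


@dataclass
class FeatureScreenResults:
    """Per-comorbidity screening report plus the surviving index set."""

    report: pd.DataFrame
    selected: np.ndarray
    alpha: float
    alpha_bonferroni: float
    n_tested: int
    prevalence_threshold: float

    def summary(self) -> str:
        lines = [
            "Univariable comorbidity screen",
            f"  tested (post prevalence filter): {self.n_tested}",
            f"  alpha={self.alpha}  Bonferroni alpha={self.alpha_bonferroni:.6g}",
            f"  survived in both halves: {len(self.selected)}",
        ]
        return "\n".join(lines)


class FeatureScreen:
    """Two-half univariable screen over matched case-control cohorts.

    Parameters
    ----------
    train, replication
        Combined matched case+control cohorts for the two halves, with an
        identical comorbidity schema.
    alpha
        Family-wise level; the per-test level is ``alpha / n_tested``
        where ``n_tested`` counts comorbidities passing the prevalence
        filter.
    prevalence_threshold
        Pooled-prevalence cutoff (both halves combined).
    """

    def __init__(
        self,
        train: Cohort,
        replication: Cohort,
        alpha: float = 0.05,
        prevalence_threshold: float = 0.01,
    ):
        if train.comorbidity_cols != replication.comorbidity_cols:
            raise ValueError("train and replication halves have different comorbidity schemas")
        self.train = train
        self.replication = replication
        self.alpha = alpha
        self.prevalence_threshold = prevalence_threshold

    def fit(self) -> FeatureScreenResults:
        pooled_X = np.vstack([self.train.X, self.replication.X])
        prevalence = pooled_X.mean(axis=0)
        passed_prev = prevalence >= self.prevalence_threshold
        n_tested = int(passed_prev.sum())
        alpha_bonf = self.alpha / n_tested if n_tested else np.nan

        rows = []
        for j, col in enumerate(self.train.comorbidity_cols):
            if passed_prev[j]:
                o_tr = univariable_or(self.train, j)
                o_re = univariable_or(self.replication, j)
                survived = (
                    not o_tr.degenerate
                    and not o_re.degenerate
                    and o_tr.p_value < alpha_bonf
                    and o_re.p_value < alpha_bonf
                )
            else:
                o_tr = o_re = OddsRatio(np.nan, np.nan, np.nan, np.nan, True)
                survived = False
            rows.append(
                {
                    "comorbidity": col,
                    "index": j,
                    "prevalence": prevalence[j],
                    "passed_prevalence": bool(passed_prev[j]),
                    "or_train": o_tr.estimate,
                    "ci_low_train": o_tr.ci_low,
                    "ci_high_train": o_tr.ci_high,
                    "p_train": o_tr.p_value,
                    "degenerate_train": o_tr.degenerate,
                    "or_repl": o_re.estimate,
                    "ci_low_repl": o_re.ci_low,
                    "ci_high_repl": o_re.ci_high,
                    "p_repl": o_re.p_value,
                    "degenerate_repl": o_re.degenerate,
                    "survived": survived,
                }
            )
        report = pd.DataFrame(rows)
        selected = report.loc[report["survived"], "index"].to_numpy()
        return FeatureScreenResults(
            report=report,
            selected=selected,
            alpha=self.alpha,
            alpha_bonferroni=alpha_bonf,
            n_tested=n_tested,
            prevalence_threshold=self.prevalence_threshold,
        )
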