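"""Standard vs. hierarchical logistic readmission models.

The *standard* model predicts 30-day readmission from comorbidities and
demographics; the *hierarchical* model adds subgroup membership as K-1
indicator variables (reference = lowest subgroup label, never a single
ordinal code). Models are trained on a 75% fold and judged on the held-out
25%: discrimination (C-statistic, DeLong CI), a paired chi-squared
contrast of C-statistics, calibration-in-the-large and slope, C within
each subgroup, and NRI/IDI reclassification against the standard model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import metrics
from .cohort import DEMOGRAPHIC_FIELDS

__all__ = [
    "ReadmissionModel",
    "ReadmissionResults",
    "split_train_validation",
    "compare_models",
    "per_subgroup_c",
    "reclassification",
]

logger = logging.getLogger(__name__)


def split_train_validation(
    data: pd.DataFrame, train_frac: float = 0.75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split into training and internal-validation folds."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(data)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return (
        data.iloc[np.sort(perm[:n_train])].reset_index(drop=True),
        data.iloc[np.sort(perm[n_train:])].reset_index(drop=True),
    )


class ReadmissionModel:
    """Binary logistic readmission model.

    Parameters
    ----------
    data : training fold; must contain the outcome column, the comorbidity
        columns, the demographic columns, and (for the hierarchical kind)
        the subgroup column.
    kind : ``"standard"`` or ``"hierarchical"``.
    comorbidity_cols : predictor columns; defaults to every ``c<j>``
        column present. An arbitrary variable list may be passed instead,
        mirroring published-model variable sets.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        kind: str = "standard",
        comorbidity_cols: list[str] | None = None,
        demographic_cols: tuple[str, ...] | list[str] = DEMOGRAPHIC_FIELDS,
        subgroup_col: str = "assigned_subgroup",
        outcome_col: str = "is_case",
    ):
        if kind not in ("standard", "hierarchical"):
            raise ValueError("kind must be 'standard' or 'hierarchical'")
        self.kind = kind
        self.data = data
        self.outcome_col = outcome_col
        self.subgroup_col = subgroup_col
        self.demographic_cols = [c for c in demographic_cols if c in data.columns]
        if comorbidity_cols is None:
            comorbidity_cols = [
                c for c in data.columns if c.startswith("c") and c[1:].isdigit()
            ]
        self.comorbidity_cols = comorbidity_cols
        if kind == "hierarchical" and subgroup_col not in data.columns:
            raise ValueError(f"hierarchical model needs a {subgroup_col!r} column")
        self.subgroup_levels = (
            sorted(data[subgroup_col].unique()) if kind == "hierarchical" else []
        )
        self._demo_levels = {
            c: sorted(map(str, data[c].unique())) for c in self.demographic_cols
        }

    # -- design matrix ---------------------------------------------------
    def design(self, data: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
        for c in self.comorbidity_cols:
            cols[c] = data[c].to_numpy(dtype=float)
        for c in self.demographic_cols:
            vals = data[c].astype(str)
            for level in self._demo_levels[c][1:]:  # first level is reference
                cols[f"{c}[{level}]"] = (vals == level).to_numpy(dtype=float)
        if self.kind == "hierarchical":
            sub = data[self.subgroup_col]
            for level in self.subgroup_levels[1:]:  # subgroup 1 is reference
                cols[f"subgroup[{level}]"] = (sub == level).to_numpy(dtype=float)
        return pd.DataFrame(cols, index=data.index)

    def fit(self, ridge_fallback: float = 1.0) -> "ReadmissionResults":
        """Maximum-likelihood fit; on separation/non-convergence, refit
        with a small recorded L2 penalty instead of failing."""
        X = self.design(self.data)
        y = self.data[self.outcome_col].astype(float).to_numpy()
        penalized = False
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = fit.mle_retvals.get("converged", True)
            if not converged or not np.isfinite(fit.params).all():
                raise RuntimeError("Logit did not converge")
            params = pd.Series(fit.params, index=X.columns)
            bse = pd.Series(fit.bse, index=X.columns)
        except Exception as err:  # separation or convergence failure
            logger.warning("ML fit failed (%s); refitting with L2 alpha=%s", err, ridge_fallback)
            penalized = True
            from sklearn.linear_model import LogisticRegression

            est = LogisticRegression(
                C=1.0 / ridge_fallback, solver="lbfgs", max_iter=5000, fit_intercept=False
            )
            est.fit(X.to_numpy(), y)
            params = pd.Series(est.coef_[0], index=X.columns)
            bse = pd.Series(np.nan, index=X.columns)
        res = ReadmissionResults(model=self, params=params, bse=bse, penalized=penalized)
        res.llf = res.log_likelihood(self.data)
        return res


@dataclass
class ReadmissionResults:
    model: ReadmissionModel
    params: pd.Series
    bse: pd.Series
    penalized: bool = False
    llf: float = np.nan
    _calibration: metrics.CalibrationResult | None = field(default=None, repr=False)

    @property
    def kind(self) -> str:
        return self.model.kind

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        X = self.model.design(data)
        return X.to_numpy() @ self.params.to_numpy()

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(data)))

    def log_likelihood(self, data: pd.DataFrame) -> float:
        y = data[self.model.outcome_col].astype(float).to_numpy()
        lp = self.linear_predictor(data)
        return float(np.sum(y * lp - np.logaddexp(0.0, lp)))

    def c_statistic(self, validation: pd.DataFrame) -> tuple[float, tuple[float, float]]:
        y = validation[self.model.outcome_col].astype(bool).to_numpy()
        return metrics.c_statistic(self.linear_predictor(validation), y)

    def calibration(self, validation: pd.DataFrame) -> metrics.CalibrationResult:
        y = validation[self.model.outcome_col].astype(bool).to_numpy()
        res = metrics.calibration(self.linear_predictor(validation), y)
        self._calibration = res
        return res

    def summary(self) -> str:
        lines = [
            f"{self.kind.capitalize()} readmission model "
            f"({'penalized' if self.penalized else 'maximum likelihood'})",
            f"  n={len(self.model.data)}  predictors={len(self.params) - 1}  "
            f"log-likelihood={self.llf:.2f}",
        ]
        coef = pd.DataFrame({"coef": self.params, "se": self.bse})
        lines.append(coef.to_string())
        return "\n".join(lines)


def compare_models(
    standard: ReadmissionResults,
    hierarchical: ReadmissionResults,
    validation: pd.DataFrame,
) -> dict:
    """Paired DeLong chi-squared contrast of the two models' C-statistics."""
    y = validation[standard.model.outcome_col].astype(bool).to_numpy()
    s_std = standard.linear_predictor(validation)
    s_hier = hierarchical.linear_predictor(validation)
    test = metrics.delong_test(s_std, s_hier, y)
    c_std, ci_std = metrics.c_statistic(s_std, y)
    c_hier, ci_hier = metrics.c_statistic(s_hier, y)
    return {
        "c_standard": c_std,
        "ci_standard": ci_std,
        "c_hierarchical": c_hier,
        "ci_hierarchical": ci_hier,
        "difference": test["difference"],
        "chi2": test["chi2"],
        "p": test["p"],
    }


def per_subgroup_c(
    results: ReadmissionResults,
    validation: pd.DataFrame,
    subgroup_col: str = "assigned_subgroup",
) -> pd.DataFrame:
    """C-statistic of one model within each subgroup's validation patients.

    Subgroups whose validation members are single-class get an undefined
    entry. These C-statistics describe different populations and are not
    comparable with each other or with the overall C.
    """
    rows = []
    for g in sorted(validation[subgroup_col].unique()):
        sub = validation[validation[subgroup_col] == g]
        y = sub[results.model.outcome_col].astype(bool).to_numpy()
        if y.all() or not y.any():
            rows.append(
                {"subgroup": g, "n": len(sub), "c": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "defined": False}
            )
            continue
        c, (lo, hi) = metrics.c_statistic(results.linear_predictor(sub), y)
        rows.append(
            {"subgroup": g, "n": len(sub), "c": c, "ci_low": lo, "ci_high": hi,
             "defined": True}
        )
    return pd.DataFrame(rows)


def reclassification(
    standard: ReadmissionResults,
    hierarchical: ReadmissionResults,
    validation: pd.DataFrame,
    cutpoints=None,
) -> dict:
    """NRI (categorical + continuous) and IDI of hierarchical vs standard.

    Computed on the validation fold only. Categorical cutpoints default to
    the tertiles of the pooled standard-model predicted risk and are
    echoed in the result.
    """
    y = validation[standard.model.outcome_col].astype(bool).to_numpy()
    p_old = standard.predict_proba(validation)
    p_new = hierarchical.predict_proba(validation)
    if cutpoints is None:
        cutpoints = np.quantile(p_old, [1 / 3, 2 / 3])
        cutpoints = np.unique(cutpoints)
    nri_res = metrics.nri(p_old, p_new, y, cutpoints=cutpoints)
    idi_res = metrics.idi(p_old, p_new, y)
    return {
        "nri_continuous": nri_res["continuous"],
        "nri_categorical": nri_res.get("categorical"),
        "idi": idi_res,
        "cutpoints": np.asarray(cutpoints, dtype=float),
    }
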