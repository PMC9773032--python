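"""Multinomial subgroup classification and subgroup readmission risk.

Once biclustering has labelled the *cases*, a multinomial logistic model
on the selected comorbidities classifies every patient — case or control —
into a subgroup; the per-subgroup case fraction is that subgroup's
readmission risk, and membership probabilities feed the importance score
IS = MP x R used to rank subgroups (and their interventions) for an
individual patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort

__all__ = [
    "SubgroupClassifier",
    "SubgroupClassifierResults",
    "ValidationSummary",
    "subgroup_risk",
    "importance_scores",
]

logger = logging.getLogger(__name__)


class SubgroupClassifier:
    """Multinomial logistic model mapping comorbidity vectors to subgroups.

    Parameters
    ----------
    X : (n, p) binary matrix of selected comorbidities (cases only).
    labels : 1-based subgroup labels from the bicluster partition.
    ridge : L2 penalty strength (0 disables); a small default keeps the
        maximum-likelihood fit finite on separable planted data.
    """

    def __init__(self, X: np.ndarray, labels: np.ndarray, ridge: float = 1e-2):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 subgroups to fit a classifier")
        small = classes[counts < 2]
        if small.size:
            raise ValueError(f"subgroup(s) {small.tolist()} have fewer than 2 members")
        self.X = X
        self.labels = labels
        self.classes = classes
        self.ridge = ridge

    def fit(self, max_iter: int = 2000) -> "SubgroupClassifierResults":
        C = 1.0 / self.ridge if self.ridge > 0 else np.inf
        est = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=1e-10)
        est.fit(self.X, self.labels)
        if est.n_iter_.max() >= max_iter:
            logger.warning("multinomial fit hit max_iter=%d before converging", max_iter)
        res = SubgroupClassifierResults(model=self, estimator=est)
        res.training_accuracy = res.accuracy(self.X, self.labels)
        return res


@dataclass
class SubgroupClassifierResults:
    model: SubgroupClassifier
    estimator: LogisticRegression
    training_accuracy: float = np.nan

    @property
    def classes(self) -> np.ndarray:
        return self.estimator.classes_

    @property
    def coefficients(self) -> pd.DataFrame:
        coefs = np.column_stack([self.estimator.intercept_, self.estimator.coef_])
        cols = ["intercept"] + [f"x{j + 1}" for j in range(self.estimator.coef_.shape[1])]
        return pd.DataFrame(coefs, index=self.classes, columns=cols)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Hard assignment by highest membership probability.

        Exact probability ties break toward the lowest subgroup index and
        raise the per-patient tie flag.
        """
        proba = self.predict_proba(X)
        best = np.argmax(proba, axis=1)  # argmax takes the first (lowest) index on ties
        ties = (proba == proba[np.arange(len(proba)), best][:, None]).sum(axis=1) > 1
        if ties.any():
            logger.info("%d patients had exact membership-probability ties", int(ties.sum()))
        return self.classes[best], proba, ties

    def accuracy(self, X: np.ndarray, labels: np.ndarray) -> float:
        assigned, _, _ = self.predict(X)
        return float(np.mean(assigned == np.asarray(labels)))

    def classify_all(self, cases: Cohort, controls: Cohort, selected: np.ndarray) -> pd.DataFrame:
        """Membership table for every case and control.

        Columns: patient_id, is_case, assigned_subgroup, tie, p_1..p_K.
        Only comorbidities enter the features; case/control status is
        never used as a predictor.
        """
        frames = []
        for cohort in (cases, controls):
            if len(cohort) == 0:
                continue
            X = cohort.X[:, selected]
            assigned, proba, ties = self.predict(X)
            block = pd.DataFrame(
                {
                    "patient_id": cohort.patient_ids,
                    "is_case": cohort.is_case,
                    "assigned_subgroup": assigned,
                    "tie": ties,
                }
            )
            for idx, cls in enumerate(self.classes):
                block[f"p_{cls}"] = proba[:, idx]
            frames.append(block)
        return pd.concat(frames, ignore_index=True)

    def internal_validation(
        self,
        n_splits: int = 1000,
        train_frac: float = 0.75,
        seed: int = 0,
        max_retries: int = 100,
    ) -> "ValidationSummary":
        """Repeated random-split validation of subgroup assignment.

        For each seeded split the model is refitted on ``train_frac`` of
        the cases and accuracy measured on both folds; splits that leave a
        subgroup out of the training fold are resampled (logged, capped).
        Accuracies are summarised in percent.
        """
        rng = np.random.default_rng(seed)
        X, labels = self.model.X, self.model.labels
        n = len(labels)
        n_train = int(round(train_frac * n))
        train_acc = np.empty(n_splits)
        test_acc = np.empty(n_splits)
        resampled = 0
        for s in range(n_splits):
            for _ in range(max_retries):
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
                if len(np.unique(labels[tr])) == len(self.model.classes):
                    break
                resampled += 1
            else:
                raise RuntimeError("could not draw a split containing every subgroup")
            res = SubgroupClassifier(X[tr], labels[tr], ridge=self.model.ridge).fit()
            train_acc[s] = res.accuracy(X[tr], labels[tr])
            test_acc[s] = res.accuracy(X[te], labels[te])
        if resampled:
            logger.info("resampled %d splits lacking a subgroup in training", resampled)
        return ValidationSummary(
            train=_acc_stats(train_acc),
            test=_acc_stats(test_acc),
            n_splits=n_splits,
            train_frac=train_frac,
            seed=seed,
        )


def _acc_stats(acc: np.ndarray) -> dict:
    pct = 100.0 * acc
    q = np.quantile(pct, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "q025": q[0],
        "q25": q[1],
        "q50": q[2],
        "q75": q[3],
        "q975": q[4],
        "mean": float(pct.mean()),
        "sd": float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
        "min": float(pct.min()),
        "max": float(pct.max()),
    }


@dataclass
class ValidationSummary:
    """Quantiles/mean/SD/range (percent correct) over repeated splits."""

    train: dict
    test: dict
    n_splits: int
    train_frac: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fold, stats in (("training", self.train), ("testing", self.test)):
            rows.append(
                {
                    "fold": fold,
                    "Q0.025": stats["q025"],
                    "Q0.25": stats["q25"],
                    "Q0.50": stats["q50"],
                    "Q0.75": stats["q75"],
                    "Q0.975": stats["q975"],
                    "mean": stats["mean"],
                    "sd": stats["sd"],
                    "range": f"{stats['min']:.4g}-{stats['max']:.4g}",
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        f = self.to_frame()
        return (
            f"Internal validation over {self.n_splits} splits "
            f"({100 * self.train_frac:.0f}/{100 * (1 - self.train_frac):.0f}):\n"
            + f.to_string(index=False)
        )


def subgroup_risk(memberships: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup readmission risk from a classified membership table.

    ``risk = n_cases / (n_cases + n_controls)``; subgroups with no
    classified members get an undefined (NaN) risk, flagged, never 0.
    """
    rows = []
    subgroups = sorted(memberships["assigned_subgroup"].unique())
    for g in subgroups:
        sub = memberships[memberships["assigned_subgroup"] == g]
        n_cases = int(sub["is_case"].sum())
        n_controls = int((~sub["is_case"].astype(bool)).sum())
        denom = n_cases + n_controls
        rows.append(
            {
                "subgroup": g,
                "n_cases": n_cases,
                "n_controls": n_controls,
                "risk": n_cases / denom if denom else np.nan,
                "defined": denom > 0,
            }
        )
    out = pd.DataFrame(rows)
    undefined = out.loc[~out["defined"], "subgroup"].tolist()
    if undefined:
        logger.warning("subgroup(s) %s have no classified members; risk undefined", undefined)
    return out


def importance_scores(probabilities: np.ndarray, risk_table: pd.DataFrame) -> pd.DataFrame:
    """Rank subgroups for one patient by IS = membership probability x risk.

    Subgroups with undefined risk are excluded from the ranking (logged).
    The sort is stable and descending, so equal scores keep subgroup-index
    order.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    table = risk_table.sort_values("subgroup").reset_index(drop=True)
    if len(probabilities) != len(table):
        raise ValueError("probability vector and risk table cover different subgroup sets")
    scores = pd.DataFrame(
        {
            "subgroup": table["subgroup"],
            "membership_probability": probabilities,
            "risk": table["risk"],
            "importance": probabilities * table["risk"].to_numpy(),
        }
    )
    undefined = scores[~np.isfinite(scores["importance"])]
    if len(undefined):
        logger.info(
            "excluding subgroup(s) %s with undefined risk from importance ranking",
            undefined["subgroup"].tolist(),
        )
    ranked = scores[np.isfinite(scores["importance"])]
    ranked = ranked.sort_values("importance", ascending=False, kind="stable").reset_index(
        drop=True
    )
    return ranked
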