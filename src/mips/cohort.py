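"""Synthetic case/control cohorts with planted comorbidity biclusters.

Real claims cohorts of this kind (hospital readmission cases matched to
non-readmitted controls, each patient described by a binary comorbidity
vector) live behind data-use agreements, so the package ships a generator
that emulates their structure: every patient belongs to one of ``K``
latent subgroups, carries each comorbidity of their subgroup's block with
probability ``p_in`` and every other comorbidity with probability
``p_out``, and is readmitted (a *case*) with a subgroup-specific
probability. Demographics are sampled independently of subgroup by
default so that demographic matching removes no subgroup signal; a
confounding switch couples them for stress tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "Cohort",
    "DEFAULT_DEMOGRAPHICS",
    "generate_cohort",
    "sample_patients",
    "split_halves",
    "simulate_logistic_outcomes",
]

#: Default categorical demographic levels with sampling weights, loosely
#: shaped like an elderly hospitalised population (age bands start at 66
#: because Medicare-style cohorts require ≥66 years at admission).
DEFAULT_DEMOGRAPHICS: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "age_band": (("66-69", "70-74", "75-79", "80-84", "85+"), (0.22, 0.26, 0.22, 0.17, 0.13)),
    "sex": (("F", "M"), (0.56, 0.44)),
    "race": (("white", "black", "hispanic", "other"), (0.80, 0.10, 0.05, 0.05)),
    "medicaid": (("no", "yes"), (0.82, 0.18)),
}

DEMOGRAPHIC_FIELDS = tuple(DEFAULT_DEMOGRAPHICS)


def default_comorbidity_log_or(d: int) -> tuple[float, ...]:
    """Cycling direct log-odds (0.4/0.7/1.0) for d comorbidities.

    Gives univariable readmission ORs in the 1.5-3 range typical of
    elderly claims cohorts, so Bonferroni screening has real signal.
    """
    return tuple((0.4, 0.7, 1.0)[j % 3] for j in range(d))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a planted-bicluster cohort.

    Parameters
    ----------
    n_cases, n_controls
        Exact number of readmitted / non-readmitted patients to return.
    n_comorbidities
        Length ``d`` of each binary comorbidity vector.
    n_subgroups
        Number ``K`` of planted subgroups; comorbidities are split into
        ``K`` contiguous blocks of size ``d // K`` with the remainder
        assigned to the last block.
    p_in, p_out
        Probability of carrying a comorbidity inside / outside the
        patient's own block; requires ``0 <= p_out < p_in <= 1``.
    subgroup_risks
        Per-subgroup readmission probability, each strictly in (0, 1).
    subgroup_weights
        Sampling weights over subgroups (uniform by default).
    demographic_levels
        Mapping field -> (levels, weights).
    confound_demographics
        If True, the first demographic field's distribution is tilted by
        subgroup (stress-test switch; default independent).
    seed
        RNG seed; generation is a pure function of (spec, seed).
    """

    n_cases: int
    n_controls: int
    n_comorbidities: int = 30
    n_subgroups: int = 4
    p_in: float = 0.4
    p_out: float = 0.05
    subgroup_risks: tuple[float, ...] = (0.12, 0.15, 0.17, 0.20)
    subgroup_weights: tuple[float, ...] | None = None
    comorbidity_log_or: tuple[float, ...] | None = None
    demographic_levels: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    confound_demographics: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("n_cases and n_controls must be non-negative")
        if self.n_subgroups < 2:
            raise ValueError("need at least 2 subgroups (K >= 2)")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if len(self.subgroup_risks) != self.n_subgroups:
            raise ValueError("subgroup_risks must have length n_subgroups")
        if not all(0.0 < r < 1.0 for r in self.subgroup_risks):
            raise ValueError("each subgroup risk must lie strictly in (0, 1)")
        if self.n_comorbidities < self.n_subgroups:
            raise ValueError("need at least one comorbidity per subgroup block")
        if self.comorbidity_log_or is not None and len(self.comorbidity_log_or) != self.n_comorbidities:
            raise ValueError("comorbidity_log_or must have length n_comorbidities")
        if self.subgroup_weights is not None:
            if len(self.subgroup_weights) != self.n_subgroups:
                raise ValueError("subgroup_weights must have length n_subgroups")
            if min(self.subgroup_weights) < 0 or sum(self.subgroup_weights) <= 0:
                raise ValueError("subgroup_weights must be non-negative and sum > 0")

    @property
    def block_bounds(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) comorbidity index range of each block."""
        d, k = self.n_comorbidities, self.n_subgroups
        size = d // k
        bounds = [(g * size, (g + 1) * size) for g in range(k)]
        # remainder comorbidities belong to the last block
        bounds[-1] = (bounds[-1][0], d)
        return bounds

    def block_of(self, j: int) -> int:
        for g, (lo, hi) in enumerate(self.block_bounds):
            if lo <= j < hi:
                return g
        raise IndexError(j)


class Cohort:
    """A patient table: demographics, case flag, binary comorbidity vector.

    Thin wrapper around a :class:`pandas.DataFrame` whose comorbidity
    columns are named ``c1 .. cd``. Construct with :func:`generate_cohort`
    or :meth:`Cohort.from_csv`.
    """

    def __init__(self, frame: pd.DataFrame):
        if "patient_id" not in frame.columns or "is_case" not in frame.columns:
            raise ValueError("cohort frame needs patient_id and is_case columns")
        if frame["patient_id"].duplicated().any():
            raise ValueError("patient_ids must be unique")
        self.frame = frame.reset_index(drop=True)
        self.comorbidity_cols = [c for c in frame.columns if _is_comorbidity_col(c)]
        vals = self.frame[self.comorbidity_cols].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("comorbidity columns must be strictly 0/1")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def d(self) -> int:
        return len(self.comorbidity_cols)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy()

    @property
    def is_case(self) -> np.ndarray:
        return self.frame["is_case"].to_numpy().astype(bool)

    @property
    def X(self) -> np.ndarray:
        """Binary comorbidity matrix, shape (n, d)."""
        return self.frame[self.comorbidity_cols].to_numpy(dtype=np.int8)

    @property
    def true_subgroup(self) -> np.ndarray | None:
        if "true_subgroup" in self.frame.columns:
            return self.frame["true_subgroup"].to_numpy()
        return None

    def cases(self) -> "Cohort":
        return Cohort(self.frame[self.frame["is_case"]])

    def controls(self) -> "Cohort":
        return Cohort(self.frame[~self.frame["is_case"].astype(bool)])

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.frame[np.asarray(mask)])

    def select_comorbidities(self, indices: Sequence[int]) -> "Cohort":
        """Keep only the comorbidity columns at 0-based ``indices``."""
        keep = [self.comorbidity_cols[i] for i in indices]
        other = [c for c in self.frame.columns if c not in self.comorbidity_cols]
        return Cohort(self.frame[other + keep])

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path, meta: Mapping | None = None) -> None:
        """Write the patient table; optional sidecar JSON with spec/seed."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        if meta is not None:
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        frame = pd.read_csv(path)
        frame["is_case"] = frame["is_case"].astype(bool)
        return cls(frame)


def _is_comorbidity_col(name: str) -> bool:
    return isinstance(name, str) and name.startswith("c") and name[1:].isdigit()


def _sample_demographics(
    rng: np.random.Generator,
    n: int,
    levels: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]],
    subgroup: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, (fieldname, (cats, weights)) in enumerate(levels.items()):
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        if subgroup is not None and i == 0:
            # confounded draw: rotate the weight vector by subgroup index
            draws = np.empty(n, dtype=object)
            for g in np.unique(subgroup):
                m = subgroup == g
                wg = np.roll(w, int(g))
                draws[m] = rng.choice(cats, size=int(m.sum()), p=wg / wg.sum())
            out[fieldname] = draws.astype(str)
        else:
            out[fieldname] = rng.choice(cats, size=n, p=w).astype(str)
    return out


def sample_patients(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` patients with *natural* (untruncated) case status.

    The case fraction within subgroup ``g`` converges to
    ``spec.subgroup_risks[g]``; :func:`generate_cohort` builds on this and
    truncates to exact case/control counts.
    """
    k = spec.n_subgroups
    weights = spec.subgroup_weights
    p = None if weights is None else np.asarray(weights, float) / np.sum(weights)
    subgroup = rng.choice(np.arange(1, k + 1), size=n, p=p)

    d = spec.n_comorbidities
    prob = np.full((n, d), spec.p_out)
    for g, (lo, hi) in enumerate(spec.block_bounds, start=1):
        prob[subgroup == g, lo:hi] = spec.p_in
    X = (rng.random((n, d)) < prob).astype(np.int8)

    risks = np.asarray(spec.subgroup_risks)[subgroup - 1]
    if spec.comorbidity_log_or is None:
        is_case = rng.random(n) < risks
    else:
        # direct comorbidity effects on top of the subgroup base risk; the
        # per-subgroup intercept is solved on the sampled batch so the mean
        # case rate within subgroup g stays at subgroup_risks[g]
        from scipy.optimize import brentq

        beta = np.asarray(spec.comorbidity_log_or, float)
        effect = X.astype(float) @ beta
        lp = np.empty(n)
        for g in range(1, spec.n_subgroups + 1):
            mask = subgroup == g
            if not mask.any():
                continue
            target = spec.subgroup_risks[g - 1]
            eff = effect[mask]

            def gap(b: float) -> float:
                return float(np.mean(1.0 / (1.0 + np.exp(-(b + eff)))) - target)

            intercept = brentq(gap, -30.0, 30.0)
            lp[mask] = intercept + eff
        is_case = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))

    demo = _sample_demographics(
        rng, n, spec.demographic_levels, subgroup if spec.confound_demographics else None
    )
    frame = pd.DataFrame({"is_case": is_case, **demo})
    for j in range(d):
        frame[f"c{j + 1}"] = X[:, j]
    frame["true_subgroup"] = subgroup
    return frame


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort with exactly ``spec.n_cases`` cases and
    ``spec.n_controls`` controls.

    Patients are drawn with natural case status and accumulated until both
    quotas are filled; the excess of the over-represented arm is
    discarded. Reproducible: a pure function of the spec (which carries
    the seed).
    """
    rng = np.random.default_rng(spec.seed)
    need_cases, need_controls = spec.n_cases, spec.n_controls
    got_cases: list[pd.DataFrame] = []
    got_controls: list[pd.DataFrame] = []
    have_cases = have_controls = 0
    total = need_cases + need_controls
    batch = max(256, int(1.5 * total))
    for _ in range(200):
        if have_cases >= need_cases and have_controls >= need_controls:
            break
        draw = sample_patients(spec, batch, rng)
        c = draw[draw["is_case"]]
        nc = draw[~draw["is_case"]]
        if have_cases < need_cases:
            got_cases.append(c.iloc[: need_cases - have_cases])
            have_cases += len(got_cases[-1])
        if have_controls < need_controls:
            got_controls.append(nc.iloc[: need_controls - have_controls])
            have_controls += len(got_controls[-1])
    else:  # pragma: no cover - guarded by spec invariants
        raise RuntimeError(
            "could not fill case/control quotas; subgroup_risks make the request infeasible"
        )
    frame = pd.concat(got_cases + got_controls, ignore_index=True)
    frame.insert(0, "patient_id", [f"P{i + 1:07d}" for i in range(len(frame))])
    return Cohort(frame)


def split_halves(cohort: Cohort, seed: int) -> tuple[Cohort, Cohort]:
    """Random disjoint 50/50 split, stratified on case/control status.

    Odd counts put the extra patient in the first half. Seeded and
    deterministic.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    idx_first: list[np.ndarray] = []
    idx_second: list[np.ndarray] = []
    for flag in (True, False):
        stratum = np.flatnonzero(cohort.is_case == flag)
        perm = rng.permutation(stratum)
        half = (len(perm) + 1) // 2
        idx_first.append(perm[:half])
        idx_second.append(perm[half:])
    first = np.sort(np.concatenate(idx_first))
    second = np.sort(np.concatenate(idx_second))
    return (
        Cohort(cohort.frame.iloc[first]),
        Cohort(cohort.frame.iloc[second]),
    )


def simulate_logistic_outcomes(
    X: np.ndarray,
    coef: Iterable[float],
    intercept: float,
    subgroup: np.ndarray | None = None,
    subgroup_offsets: Iterable[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw binary outcomes from a logistic model on a comorbidity matrix.

    Supports the two stress designs used to probe model comparison: a
    purely additive outcome (``subgroup_offsets=None``) and one with
    subgroup-specific log-odds offsets that no additive main-effect model
    can fully absorb. ``subgroup`` labels are 1-based.
    """
    rng = np.random.default_rng(seed)
    lp = intercept + np.asarray(X, float) @ np.asarray(list(coef), float)
    if subgroup_offsets is not None:
        if subgroup is None:
            raise ValueError("subgroup labels required with subgroup_offsets")
        offsets = np.asarray(list(subgroup_offsets), float)
        lp = lp + offsets[np.asarray(subgroup) - 1]
    p = 1.0 / (1.0 + np.exp(-lp))
    return rng.random(len(p)) < p
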