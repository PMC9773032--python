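"""Exact 1:1 case-control matching on demographic strata."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["MatchedSet", "match_controls"]

logger = logging.getLogger(__name__)


@dataclass
class MatchedSet:
    """Result of 1:1 exact matching.

    ``pairs`` holds (case_id, control_id) tuples; every control is used at
    most once and each pair agrees exactly on all ``matching_keys``.
    Cases that found no stratum-mate are listed in ``unmatched_cases``
    rather than silently dropped.
    """

    pairs: list[tuple[str, str]]
    matching_keys: list[str]
    unmatched_cases: list[str]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list[str]:
        out: list[str] = []
        for c, k in self.pairs:
            out.append(c)
            out.append(k)
        return out

    def to_cohort(self, cases: Cohort, control_pool: Cohort) -> Cohort:
        """Assemble the combined matched case+control cohort."""
        frame = pd.concat([cases.frame, control_pool.frame], ignore_index=True)
        keep = frame[frame["patient_id"].isin(self.matched_ids())]
        return Cohort(keep)


def match_controls(
    cases: Cohort,
    control_pool: Cohort,
    keys: list[str],
    seed: int = 0,
) -> MatchedSet:
    """Greedy 1:1 exact matching of controls to cases within demographic strata.

    Within each stratum (joint level of ``keys``), controls are drawn
    uniformly at random without replacement; the draw is seeded. Cases in
    strata with too few controls are returned as unmatched (pigeonhole:
    a stratum with ``c`` cases and ``k < c`` controls yields ``c - k``
    unmatched cases).
    """
    if len(control_pool) == 0:
        raise ValueError("control pool is empty")
    for key in keys:
        if key not in cases.frame.columns or key not in control_pool.frame.columns:
            raise KeyError(f"matching key {key!r} absent from cohort schema")

    rng = np.random.default_rng(seed)
    pool = control_pool.frame
    controls_by_stratum: dict[tuple, list[str]] = {}
    for pid, stratum in zip(pool["patient_id"], zip(*(pool[k] for k in keys))):
        controls_by_stratum.setdefault(stratum, []).append(pid)
    for stratum in sorted(controls_by_stratum):
        rng.shuffle(controls_by_stratum[stratum])

    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    case_frame = cases.frame.sort_values("patient_id")
    strata = list(zip(*(case_frame[k] for k in keys)))
    for case_id, stratum in zip(case_frame["patient_id"], strata):
        available = controls_by_stratum.get(stratum)
        if available:
            pairs.append((case_id, available.pop()))
        else:
            unmatched.append(case_id)
    if unmatched:
        logger.info("matching left %d cases unmatched", len(unmatched))
    return MatchedSet(pairs=pairs, matching_keys=list(keys), unmatched_cases=unmatched)
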