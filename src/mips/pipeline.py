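"""End-to-end orchestration of the three modelling steps.

``run_pipeline`` wires the stages together: simulate (or load) a cohort,
match controls, screen comorbidities, bicluster the training-half cases,
test significance and replication, classify everyone into subgroups,
compute subgroup risks, render the annotated network, and fit/compare the
standard and hierarchical readmission models. Every stage writes a
standard-format artifact into the run directory and appends to a plain
run log; one master seed deterministically spawns per-stage seeds so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import predict as predict_mod
from .bipartite import BiclusterModel, BipartiteGraph, replication_test
from .classify import SubgroupClassifier, importance_scores, subgroup_risk
from .cohort import (
    Cohort,
    CohortSpec,
    default_comorbidity_log_or,
    generate_cohort,
    split_halves,
)
from .matching import match_controls
from .screening import FeatureScreen, drop_empty_patients
from .viz import annotate_network, layout_network, write_graphml

__all__ = ["RunConfig", "RunLog", "run_pipeline", "stage_seeds"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "matching",
    "screening",
    "bicluster",
    "replication",
    "classify",
    "predict",
)


@dataclass
class RunConfig:
    """Configuration of a full run; echoed verbatim into the run log."""

    seed: int
    cohort_path: str | None = None
    # synthetic spec (used when cohort_path is None)
    n_cases: int = 2000
    n_controls: int = 10000
    n_comorbidities: int = 30
    n_subgroups: int = 4
    p_in: float = 0.4
    p_out: float = 0.05
    subgroup_risks: tuple[float, ...] = (0.12, 0.15, 0.17, 0.20)
    # direct comorbidity log-odds for readmission ("cycle" = repeat
    # 0.4/0.7/1.0 across comorbidities, giving univariable ORs in the
    # 1.5-3 range typical of claims cohorts; None = subgroup risk only)
    comorbidity_log_or: tuple[float, ...] | str | None = "cycle"
    # analysis knobs
    alpha: float = 0.05
    prevalence_threshold: float = 0.01
    matching_keys: tuple[str, ...] = ("age_band", "sex", "race", "medicaid")
    restarts: int = 20
    n_perm: int = 1000
    perm_restarts: int = 4
    n_splits: int = 1000
    visual_split_frac: float = 0.5
    train_frac: float = 0.75
    nri_cutpoints: tuple[float, ...] | None = None
    explode_radius: float = 0.5
    ridge: float = 1e-2
    out_dir: str = "mips_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        for frac in (self.visual_split_frac, self.train_frac):
            if not 0 < frac < 1:
                raise ValueError("split fractions must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        for key in ("subgroup_risks", "matching_keys", "nri_cutpoints"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


class RunLog:
    """Timestamped stage records sufficient to re-derive every table."""

    def __init__(self) -> None:
        self.records: list[str] = []

    def add(self, stage: str, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.records.append(f"{stamp} [{stage}] {message}")
        logger.info("[%s] %s", stage, message)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.records) + "\n")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministically spawn a sub-2^31 seed per stage from the master."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31 - 1))
        for stage, child in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict also written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    seeds = stage_seeds(config.seed)
    log.add("config", json.dumps(asdict(config), default=str))
    log.add("config", f"stage seeds: {seeds}")

    # --- stage 1: cohort ------------------------------------------------
    if config.cohort_path is not None:
        if not Path(config.cohort_path).exists():
            raise FileNotFoundError(f"input cohort not found: {config.cohort_path}")
        cohort = Cohort.from_csv(config.cohort_path)
        log.add("simulate", f"loaded cohort from {config.cohort_path}: n={len(cohort)}")
    else:
        betas = config.comorbidity_log_or
        if isinstance(betas, str):
            if betas != "cycle":
                raise ValueError("comorbidity_log_or must be 'cycle', a vector, or None")
            betas = default_comorbidity_log_or(config.n_comorbidities)
        spec = CohortSpec(
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            n_comorbidities=config.n_comorbidities,
            n_subgroups=config.n_subgroups,
            p_in=config.p_in,
            p_out=config.p_out,
            subgroup_risks=config.subgroup_risks,
            comorbidity_log_or=betas,
            seed=seeds["simulate"],
        )
        cohort = generate_cohort(spec)
        cohort.to_csv(out / "cohort.csv", meta={"spec": asdict(spec)})
        log.add(
            "simulate",
            f"generated cohort: {spec.n_cases} cases / {spec.n_controls} controls, "
            f"d={spec.n_comorbidities}, K={spec.n_subgroups}",
        )
    cases, controls = cohort.cases(), cohort.controls()

    # --- stage 2: split + matching -------------------------------------
    cases_train, cases_repl = split_halves(cases, seeds["matching"])
    matched_train = match_controls(
        cases_train, controls, list(config.matching_keys), seed=seeds["matching"]
    )
    used = set(cid for _, cid in matched_train.pairs)
    remaining = controls.subset(~np.isin(controls.patient_ids, list(used)))
    matched_repl = match_controls(
        cases_repl, remaining, list(config.matching_keys), seed=seeds["matching"] + 1
    )
    log.add(
        "matching",
        f"train half: {matched_train.n_pairs} pairs ({len(matched_train.unmatched_cases)} "
        f"unmatched); replication half: {matched_repl.n_pairs} pairs "
        f"({len(matched_repl.unmatched_cases)} unmatched)",
    )

    # --- stage 3: feature screening ------------------------------------
    train_matched = matched_train.to_cohort(cases_train, controls)
    repl_matched = matched_repl.to_cohort(cases_repl, remaining)
    screen = FeatureScreen(
        train_matched,
        repl_matched,
        alpha=config.alpha,
        prevalence_threshold=config.prevalence_threshold,
    ).fit()
    screen.report.to_csv(out / "feature_report.csv", index=False)
    selected = screen.selected
    if selected.size == 0:
        raise RuntimeError("screening stage failed: no comorbidity survived")
    log.add(
        "screening",
        f"{screen.n_tested} tested at alpha_bonf={screen.alpha_bonferroni:.3g}; "
        f"{len(selected)} survived both halves",
    )

    # --- stage 4: biclustering (training half, cases only) --------------
    n_before = len(cases_train)
    cases_train_f = drop_empty_patients(cases_train, selected)
    log.add("bicluster", f"dropped {n_before - len(cases_train_f)} empty patients (train half)")
    graph = BipartiteGraph.from_cohort(cases_train_f, selected)
    bic = BiclusterModel(graph).fit(restarts=config.restarts, seed=seeds["bicluster"])
    sig = bic.test_significance(
        n_perm=config.n_perm, seed=seeds["bicluster"], restarts=config.perm_restarts
    )
    bic.to_frame().to_csv(out / "partition.csv", index=False)
    write_graphml(
        graph, bic.partition, out / "network.graphml", q=bic.q, z=sig.z, p=sig.p_empirical
    )
    log.add("bicluster", bic.summary().replace("\n", " | "))

    # --- stage 5: replication ------------------------------------------
    n_before = len(cases_repl)
    cases_repl_f = drop_empty_patients(cases_repl, selected)
    log.add(
        "replication", f"dropped {n_before - len(cases_repl_f)} empty patients (replication half)"
    )
    graph_repl = BipartiteGraph.from_cohort(cases_repl_f, selected)
    bic_repl = BiclusterModel(graph_repl).fit(
        restarts=config.restarts, seed=seeds["replication"]
    )
    repl = replication_test(
        bic.partition.comorbidity_labels,
        bic_repl.comorbidity_labels_for(graph.comorbidity_ids),
        n_perm=config.n_perm,
        seed=seeds["replication"],
    )
    log.add("replication", repl.summary())

    # --- stage 6: classification ---------------------------------------
    clf = SubgroupClassifier(
        graph.A.astype(float), bic.partition.patient_labels, ridge=config.ridge
    ).fit()
    validation = clf.internal_validation(
        n_splits=config.n_splits, train_frac=config.train_frac, seed=seeds["classify"]
    )
    validation.to_frame().to_csv(out / "validation_summary.csv", index=False)
    memberships = clf.classify_all(cases, controls, selected)
    memberships.to_csv(out / "memberships.csv", index=False)
    risks = subgroup_risk(memberships)
    risks.to_csv(out / "subgroup_risks.csv", index=False)
    log.add(
        "classify",
        f"training accuracy={100 * clf.training_accuracy:.2f}%; "
        f"median testing accuracy={validation.test['q50']:.2f}%",
    )

    # --- annotated network figure --------------------------------------
    layout = layout_network(
        graph, bic.partition, explode_radius=config.explode_radius, seed=seeds["bicluster"]
    )
    fig, annotation = annotate_network(
        graph, bic.partition, layout, screen.report, risks, path=out / "network.svg"
    )
    import matplotlib.pyplot as plt

    plt.close(fig)
    annotation.to_csv(out / "network_annotation.csv", index=False)

    # --- stage 7: prediction -------------------------------------------
    joined = cohort.frame.merge(
        memberships[["patient_id", "assigned_subgroup"]], on="patient_id", how="inner"
    )
    train_df, valid_df = predict_mod.split_train_validation(
        joined, train_frac=config.train_frac, seed=seeds["predict"]
    )
    selected_cols = [cohort.comorbidity_cols[i] for i in selected]
    std = predict_mod.ReadmissionModel(
        train_df, kind="standard", comorbidity_cols=selected_cols
    ).fit()
    hier = predict_mod.ReadmissionModel(
        train_df, kind="hierarchical", comorbidity_cols=selected_cols
    ).fit()
    comparison = predict_mod.compare_models(std, hier, valid_df)
    cal_std = std.calibration(valid_df)
    cal_hier = hier.calibration(valid_df)
    per_sub = predict_mod.per_subgroup_c(std, valid_df)
    per_sub.to_csv(out / "per_subgroup_c.csv", index=False)
    recls = predict_mod.reclassification(
        std, hier, valid_df, cutpoints=config.nri_cutpoints
    )
    log.add(
        "predict",
        f"C standard={comparison['c_standard']:.3f} "
        f"hierarchical={comparison['c_hierarchical']:.3f} "
        f"chi2={comparison['chi2']:.3f} P={comparison['p']:.3g}",
    )

    # --- summary --------------------------------------------------------
    summary = {
        "n_patients": len(cohort),
        "n_cases": len(cases),
        "n_controls": len(controls),
        "n_selected_comorbidities": int(len(selected)),
        "alpha_bonferroni": screen.alpha_bonferroni,
        "biclusters_k": int(bic.k),
        "modularity_q": bic.q,
        "modularity_z": sig.z,
        "modularity_p_empirical": sig.p_empirical,
        "replication_ri": repl.ri,
        "replication_z": repl.z,
        "replication_p_empirical": repl.p_empirical,
        "classifier_training_accuracy_pct": 100 * clf.training_accuracy,
        "classifier_median_testing_accuracy_pct": validation.test["q50"],
        "subgroup_risks": {
            int(r["subgroup"]): (None if not np.isfinite(r["risk"]) else float(r["risk"]))
            for _, r in risks.iterrows()
        },
        "c_standard": comparison["c_standard"],
        "ci_standard": list(comparison["ci_standard"]),
        "c_hierarchical": comparison["c_hierarchical"],
        "ci_hierarchical": list(comparison["ci_hierarchical"]),
        "compare_chi2": comparison["chi2"],
        "compare_p": comparison["p"],
        "calibration_standard": {"citl": cal_std.citl, "slope": cal_std.slope},
        "calibration_hierarchical": {"citl": cal_hier.citl, "slope": cal_hier.slope},
        "nri_continuous": recls["nri_continuous"].estimate,
        "nri_categorical": (
            None if recls["nri_categorical"] is None else recls["nri_categorical"].estimate
        ),
        "idi": recls["idi"].estimate,
        "nri_cutpoints": recls["cutpoints"].tolist(),
        "stage_seeds": seeds,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    comparison_table = pd.DataFrame(
        [
            {
                "measure": "NRI categorical",
                "estimate": summary["nri_categorical"],
                "z": None
                if recls["nri_categorical"] is None
                else recls["nri_categorical"].z,
                "p": None
                if recls["nri_categorical"] is None
                else recls["nri_categorical"].p,
            },
            {
                "measure": "NRI continuous",
                "estimate": recls["nri_continuous"].estimate,
                "z": recls["nri_continuous"].z,
                "p": recls["nri_continuous"].p,
            },
            {
                "measure": "IDI",
                "estimate": recls["idi"].estimate,
                "z": recls["idi"].z,
                "p": recls["idi"].p,
            },
        ]
    )
    comparison_table.to_csv(out / "model_comparison.csv", index=False)
    log.write(out / "run_log.txt")

    # expose fitted objects for programmatic use
    summary["_objects"] = {
        "screen": screen,
        "bicluster": bic,
        "significance": sig,
        "replication": repl,
        "classifier": clf,
        "validation": validation,
        "memberships": memberships,
        "risks": risks,
        "standard": std,
        "hierarchical": hier,
        "reclassification": recls,
        "importance_scores": importance_scores,
    }
    return summary
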