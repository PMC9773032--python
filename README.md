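# mips — modelling and interpreting patient subgroups

`mips` implements a three-step framework for discovering, classifying and
exploiting patient subgroups in hospital-readmission cohorts, where each
patient is described by a binary comorbidity vector and a 30-day
unplanned-readmission flag. It is aimed at biostatisticians and health-services
researchers who want the whole chain — subgroup discovery, membership
classification, and risk-prediction comparison — reproducible from one seed.

1. **Visual-analytical modelling.** Readmitted patients (cases) and their
   comorbidities form a bipartite graph with incidence `A ∈ {0,1}^{n×d}`.
   Biclusters (a patient subgroup plus its co-occurring comorbidities) are
   found by maximising Barber's bipartite modularity

   &nbsp;&nbsp;&nbsp;&nbsp;Q = (1/m) Σᵢⱼ (Aᵢⱼ − kᵢdⱼ/m) δ(gᵢ, gⱼ),

   with BRIM-style alternating label sweeps from many seeded restarts; the
   number of biclusters K is emergent, never user-fixed. Significance comes
   from a degree-preserving permutation test (re-optimising Q on each rewired
   graph), replication from the Rand index between the comorbidity labellings
   of two independent cohort halves against a label-shuffle null. Upstream,
   comorbidities are screened by 1:1 demographically matched controls,
   a ≥1% prevalence filter, and Bonferroni-corrected univariable odds ratios
   required significant in *both* halves.
2. **Classification modelling.** A multinomial logistic model on the selected
   comorbidities assigns every patient — case or control — to a subgroup by
   highest membership probability, validated by repeated 75/25 splits; the
   per-subgroup case fraction is that subgroup's readmission risk, and
   IS = MP × R (membership probability × subgroup risk) ranks subgroups per
   patient.
3. **Prediction modelling.** A *standard* binary logistic model (comorbidities
   + demographics) is compared with a *hierarchical* one (adding K−1 subgroup
   indicators) on a held-out fold via the C-statistic (DeLong CI and paired
   chi-squared contrast), calibration-in-the-large and slope, per-subgroup
   C-statistics, and NRI/IDI reclassification.

Because the claims data this kind of analysis targets sit behind data-use
agreements, the package ships a synthetic cohort generator with planted
biclusters (`p_in`/`p_out` within/outside-block comorbidity prevalence,
subgroup-specific readmission risks in the 12–20% range, optional direct
comorbidity effects) so every stage is testable end to end.

## Worked example

```python
from mips import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=7, n_perm=50, n_splits=100,
                                 out_dir="mips_run"))
print(summary["biclusters_k"], round(summary["modularity_q"], 3),
      round(summary["modularity_z"], 1))
print(round(summary["replication_ri"], 3), round(summary["replication_z"], 2))
print(summary["classifier_median_testing_accuracy_pct"])
print(round(summary["c_standard"], 3), round(summary["c_hierarchical"], 3),
      round(summary["compare_p"], 2))
```

prints

```
3 0.408 36.1
1.0 9.03
100.0
0.714 0.715 0.23
```

Read: on the comorbidities surviving the screen, the biclustering found K=3
subgroups with modularity Q=0.408, far above the degree-preserving null
(z≈36); the comorbidity co-clustering replicated exactly in the second cohort
half (RI=1.0, z≈9); the classifier assigned held-out cases to their subgroup
with 100% median accuracy; and the hierarchical readmission model did not
significantly improve on the standard model's C-statistic (0.715 vs 0.714,
P=.23) — expected here, because the generated outcome is largely additive in
the comorbidities. `mips_run/` also receives the feature
report, partition table, GraphML network, exploded-layout SVG with
OR-ranked comorbidity labels and subgroup risks, membership and risk tables,
and a plain-text run log with per-stage seeds.

The same stages are available as a CLI
(`mips simulate | select-features | bicluster | classify | predict | report | run`),
each stage reading its predecessors' files from a shared run directory.

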