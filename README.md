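# kinrisk

Joint analysis of a **weighted family risk score (FamRS)** and a
**genome-wide polygenic score (PGS)** for type 2 diabetes (T2D) risk in
population-based cohorts — with a liability-threshold family simulator so
the whole pipeline is testable without access to restricted cohort data.

Family history reflects shared genetics *and* shared environment, so it is
not made redundant by a polygenic score. `kinrisk` quantifies the
independent and combined contributions of both measures to prevalent and
incident T2D risk: score computation, IPCW-weighted logistic modelling,
top-percentile and age-stratified contrasts, and
discrimination/reclassification statistics.

## The two scores

**FamRS** compares the onset-weighted number of affected first-degree
relatives with the number expected given family size and the participant's
age:

    FamRS = W_obs / E_exp,
    W_obs = Σ_affected w(onset),   E_exp = Σ_all relatives e(age band, relation)

where onset weights satisfy w(<60) ≥ w(unknown) ≥ w(≥60) > 0 and the
expected per-relative risk e rises with the participant's 10-year age band.
Categories: average (≤ 0.5), positive (0.5–1], strong positive (1–2], very
strong positive (> 2); analyses usually merge positive + strong positive
(FamRS 2) against very strong positive (FamRS 3).

**PGS** is the classical dosage sum PGS_i = Σ_j d_ij · w_j over a
PGS-Catalog-style scoring file, with allele harmonisation against the VCF
(effect/other vs REF/ALT, strand-ambiguous variants excluded by default),
in-sample standardisation, 5% percentile groups and top-q% flags
(q ∈ {20, 10, 5, 1}).

**Models.** Logistic regressions of prevalent and incident T2D on each
score: unadjusted; adjusted for sex, age, BMI, physical activity; and
mutually adjusted for the other score. Incident analyses exclude prevalent
cases and use inverse-probability-of-censoring weights 1/Ŝ_C(t−) from a Cox
model of death/loss to follow-up. Discrimination and reclassification via
ROC/AUC (Youden best threshold), continuous NRI, and IDI.

**Simulator.** Families (two founder parents, Mendelian transmission to an
index participant and siblings) with liability
L = z_PGS·√(h²·capture) + G_resid + C + E, where C is a family-shared
environment component and G_resid the uncaptured polygenic remainder; a
Weibull proportional-hazards onset model calibrated to ~8.3% prevalent and
~5.3% incident disease over ~11 years of follow-up.

## Worked example

```bash
kinrisk run-all --seed 1 --out demo_out
```

simulates 3,000 families and runs every stage. On this run the cohort
summary reports n = 3000, 8.4% prevalent and 5.6% incident cases, mean age
58.3, median follow-up 11 years. The main results table
(`results_main.tsv`) contains, among others:

```
outcome    exposure adjustment  term    OR    95% CI        p
prevalent  pgs      unadjusted  pgs_z   1.80  [1.58, 2.06]  7.6e-18
prevalent  pgs      mutual      pgs_z   1.79  [1.55, 2.06]  6.7e-16
prevalent  famrs    unadjusted  famrs3  2.34  [1.74, 3.15]  2.1e-08
prevalent  famrs    mutual      famrs3  1.65  [1.21, 2.25]  1.7e-03
```

Read: the per-sd PGS effect is essentially unchanged by adjustment, while
the very-strong-family-risk odds ratio attenuates once the PGS is in the
model (2.34 → 1.65) but stays clearly above 1 — the share of family history
that is *shared genetics* is absorbed by the PGS, the rest (shared
environment) is not. Top-percentile contrasts rise toward the upper tail
(top 20%: OR 2.74; top 10%: OR 3.64 for prevalent disease), and
`reclassification.json` reports AUCs (PGS 0.654, FamRS 0.599), the
continuous NRI decomposition (events 0.209 + non-events 0.280 = 0.489
overall), IDI 0.040, and the weak FamRS–PGS rank correlation
(r²_Spearman = 0.034).

Every stage can also run standalone on real data in the same dialects
(cohort TSV, family-history TSV, VCF with DS/GT, scoring TSV):

```bash
kinrisk pgs --vcf genotypes.vcf --score-file weights.tsv --out out/
kinrisk famrs --cohort cohort.tsv --family-history famhist.tsv --out out/
kinrisk analyze --cohort cohort.tsv --famrs out/famrs.tsv --pgs out/pgs.tsv --out out/
```

## Layout

- `src/kinrisk/simulate.py` — family cohort simulator and calibration
- `src/kinrisk/famrs.py` — family risk score
- `src/kinrisk/pgs.py` — polygenic score engine
- `src/kinrisk/models.py` — logistic model grid, IPCW
- `src/kinrisk/discrimination.py` — ROC/AUC, continuous NRI, IDI, Spearman
- `src/kinrisk/pipeline.py`, `cli.py` — orchestration and `kinrisk` CLI
- `docs/methods.md` — model assumptions, defaults, and design notes
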