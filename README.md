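# patchpk

Analysis pipeline for two linked questions about transdermal fentanyl in
cancer pain management:

1. **Animal arm.** How does type-2 diabetes change the skin absorption of
   transdermal fentanyl?  Plasma concentration–time profiles from
   Goto-Kakizaki (GK, diabetic) and Wistar (control) rats after an IV bolus
   (10 µg/kg) and a transdermal patch (160 µg, removed at 24 h) are analysed
   by model-independent moment analysis, the absorption rate constant *k*ₐ
   is fitted under flip-flop kinetics, and bioavailability is decomposed
   into patch release and skin permeation.
2. **Clinical arm.** Is the dose-*titration period* of transdermal fentanyl
   shorter in patients with diabetes?  The titration period is extracted
   from daily medication records by a rule (first day ending 5 consecutive
   days with no dose change and ≤ 3 rescue doses/day), dichotomised at
   ≤ 5 vs ≥ 6 days, and related to demographics and ICD-10 comorbidities by
   univariate logistic screening (p < 0.1) followed by a multivariate
   adjusted-odds-ratio (AOR) model.

Because the underlying animal and patient data are not public, the package
ships synthetic-data generators (`patchpk.simulate`) whose defaults encode
the published study conditions (group-mean PK parameters, sampling
schedules, cohort covariate distributions, comorbidity prevalences and
outcome model), so every stage runs end to end and its estimators can be
validated by parameter recovery.

## The models

**IV bolus, one compartment:** C(t) = (D/V_d)·e^(−kₑt), giving
AUC₀₋∞ = D/(kₑ·V_d).  Moment analysis estimates AUC and AUMC by
linear-up/log-down trapezoids with an exponential tail from the terminal
slope λ_z, then CL_tot = D/AUC, MRT = AUMC/AUC, Vd_ss = CL_tot·MRT.

**Transdermal, first-order depot (Bateman):**

    C(t) = F·D·kₐ / (V_d·(kₐ − kₑ)) · (e^(−kₑt) − e^(−kₐt))

Skin absorption is much slower than elimination (kₐ ≪ kₑ), so the kinetics
*flip-flop*: the terminal half-life is ln2/kₐ (≈ 30 h here), not ln2/kₑ.
`fit_ka` estimates kₐ alone by bounded least squares, with kₑ and Vd_ss
fixed from the IV arm and the subject's own bioavailability F fixed from
the AUC ratio.

**Bioavailability decomposition:** F = (AUC_td/dose_td,kg)/(AUC_iv/dose_iv)
against the group-mean IV AUC; patch release F_a = (X_unused − X_used)/X_unused
from residual patch content; skin availability F_skin = F/F_a.

**Clinical outcome model:** logit P(titration ≥ 6 days) = β₀ + Σ βⱼxⱼ over
comorbidity indicators; OR/AOR = exp(β) with Wald 95% CIs.

## Worked example

Animal arm, five virtual rats per strain with 10% proportional assay error:

```python
from patchpk.report import analyze_rat_group, pk_group_comparison
from patchpk.simulate import GK, WISTAR, simulate_rat

w = simulate_rat(WISTAR, 5, error_cv=0.10, seed=1)
g = simulate_rat(GK, 5, error_cv=0.10, seed=2)
tw = analyze_rat_group(w.iv_profiles, w.td_profiles, w.residuals)
tg = analyze_rat_group(g.iv_profiles, g.td_profiles, g.residuals)
print(pk_group_comparison(tw, tg, "wistar", "gk").round(3))
```

prints (abridged):

```
    parameter  wistar_mean  wistar_sd  gk_mean  gk_sd  p_value
       CL_tot        1.836      0.200    1.723  0.347    0.551
          k_a        0.022      0.004    0.034  0.006    0.009
        F_pct       56.008     18.813   49.086 12.926    0.519
      F_a_pct       64.517      5.994   79.280 10.776    0.035
```

The recovered absorption rate constant is ~1.5-fold higher in the virtual
diabetic strain (k_a 0.034 vs 0.022 /hr, Welch p = 0.009) with a higher
patch-release fraction F_a but no clearance or overall-F difference — the
qualitative pattern the generators encode.  The same chain is available
from the shell (`patchpk simulate-rat | nca | bioavail | fit-ka | report-pk`).

Clinical arm:

```bash
patchpk simulate-cohort --seed 1 --out-dir demo
patchpk titrate --cohort demo/cohort.csv --records demo/daily_records.csv \
    --out demo/report.json
```

For this seed the 387-patient report shows 277 patients stabilised within
5 days and 110 taking 6 days or more (range 5–22), and the univariate
screen passes 4 factors to the multivariate model, e.g.
`C67: AOR 5.546 (1.567–19.635), p = 0.008`.  Which comorbidities survive
screening varies from cohort to cohort at n = 387 — that sampling
variability is exactly what the replicate-recovery experiment below
quantifies.

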