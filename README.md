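# ibdqsp

Quantitative systems pharmacology of Crohn's disease: a mechanistic
immune-network ODE model with antibody pharmacokinetics and drug–cytokine
binding, virtual patient populations matched to published trial baselines,
in-silico biomarker trials with responder stratification, and
combination-therapy prediction.

## Who this is for

Clinical pharmacologists and modellers who want to ask population-level
questions of an inflammatory bowel disease network — *how much will median
CRP fall under this regimen? which biomarker profile marks an anti-TNF
responder? what would an anti-TNF + anti-IL-12p40 combination do?* — when
the only available clinical inputs are the summary statistics printed in
trial reports (baseline medians and IQRs, arm-level percent changes),
never patient-level data.

## The model in brief

A single-compartment ODE network couples innate activation, T-helper
differentiation and their cytokines to the two clinical readouts:

* TNFα activates dendritic cells (iDC→eDC), macrophages (M0→M1) and
  neutrophils (Neu→Neu_a); these cells secrete TNFα, IL-6, IL-8, IL-12,
  IL-23 and GM-CSF, closing a saturating feedback loop.
* IL-12 drives Th0→Th1→IFNγ; IL-23 (and IL-6) drive Th0→Th17→IL-17/IL-22;
  Treg restrains differentiation; IFNγ and IL-17 feed back onto macrophage
  and neutrophil activation.
* CRP (mg/L) is produced under saturating IL-6 drive,
  `dCRP/dt = p_CRP · [IL6f]/(Km + [IL6f]) + b_CRP − k_deg·CRP`;
  FCP (mg/kg) is driven by activated neutrophils and IL-8.

Drugs enter through closed-form two-compartment PK (identical profile for
every subject in an arm) and quasi-equilibrium binding: the free cytokine
L solves L² + (K_d + B − T)L − K_d·T = 0 with B = 2 × antibody (nM), and
the free *fraction* L/T multiplies that cytokine wherever it acts
(ustekinumab → IL-12 + IL-23; brazikumab/risankizumab → IL-23;
infliximab → TNFα; PF-04236921 → IL-6).

Virtual patients differ only in mechanistic parameters (log-uniform
±10-fold on 15 designated constants, filtered to physiological baselines);
trial populations are resampled from that database until their baseline
CRP/FCP summaries match the statistics — median+IQR, mean+SD or
median+range — that the simulated trial reported. A small calibration
(`model.fit`) tunes the anti-IL-6 affinity and the CRP floor against the
printed week-12 CRP dose–response. See `docs/methods.md` for the full
account.

## Worked example

```python
from ibdqsp import CrohnsQSPModel
from ibdqsp.calibrate import default_anti_il6_targets
from ibdqsp.synthetic import (make_paper_defaults, make_trial_fixture,
                              baseline_targets_from_fixture)

model = CrohnsQSPModel()

# 1. plausible-patient database and a trial-matched population
cohort = model.generate_population(600, seed=1)
fixture = make_trial_fixture(seed=1, n_per_arm=200)   # synthetic trial report
population = model.select_population(
    cohort, baseline_targets_from_fixture(fixture), 200, seed=1)

# 2. calibrate to the printed anti-IL-6 week-12 CRP dose-response
surrogate = population.subset(population.ids[::3][:60])
result = model.fit(default_anti_il6_targets(), surrogate,
                   ["Kd:PF-04236921", "b_CRP"], seed=1, maxfev=40)
print(result.summary())

# 3. simulate the combination on the same matched population
regs = make_paper_defaults()["regimens"]
inf, ust, combo = result.model.simulate_combination(
    population, regs["infliximab_induction"], regs["ustekinumab_6mgkg"])
for arm in (inf, ust, combo):
    print(f"{arm.name:28s} median CRP day 84: "
          f"{arm.series('CRP').iloc[:, -1].median():5.2f} mg/L")
```

Output from this exact script (seed 1):

```
Calibration result
==================================================================
objective: 0.000328401   evaluations: 41   seed: 1

parameter                    initial      fitted    ratio
---------------------------------------------------------
Kd:PF-04236921                   0.1      0.7963    7.963
b_CRP                           0.45      0.2755    0.612

target                                          obs     sim
-----------------------------------------------------------
anti-IL-6 200 mg: median % CRP reduction wk12     95    93.6
anti-IL-6 50 mg: median % CRP reduction wk12   86.3   87.43
anti-IL-6 10 mg: median % CRP reduction wk12   65.6   65.39
infliximab                   median CRP day 84:  3.16 mg/L
ustekinumab                  median CRP day 84:  9.71 mg/L
infliximab+ustekinumab       median CRP day 84:  2.72 mg/L
```

The calibration tables read: the fitted anti-IL-6 affinity (0.8 nM) and
CRP production floor reproduce the three printed clinical reductions to
within ~2 percentage points on the calibration surrogate; on the full
population, anti-TNF alone leaves median CRP just above the 3 mg/L
normalisation cutoff, while the combination crosses it — the package's
in-silico version of the reported combination benefit.

A command-line interface wraps the same pipeline
(`ibdqsp run --seed 1 --out results/`, stages
`generate|select|calibrate|simulate-trial|classify-responders|simulate-combination`),
writing CSV/JSON artifacts plus a hash manifest.

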