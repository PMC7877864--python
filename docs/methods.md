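# Methods

`ibdqsp` implements a quantitative systems pharmacology (QSP) workflow for
Crohn's disease: a mechanistic immune-network ODE model coupled to antibody
pharmacokinetics and drug–cytokine binding, virtual patient populations
matched to published trial baselines, longitudinal biomarker trial
simulation, biomarker-cutoff responder stratification, and in-silico
combination therapy. This note records the model, its assumptions, the
parameters that matter, and the choices made where the design was open.

## The immune network

The model tracks 22 species in one well-stirred serum/tissue compartment:

* **Cells** (arbitrary density units): naive T (Th0), Th1, Th17, Treg, NK1,
  immature and effector dendritic cells (iDC, eDC), resting and classically
  activated macrophages (M0, M1), resting and activated neutrophils
  (Neu, Neu_a).
* **Cytokines** (pg/mL): TNFα, IL-6, IL-8, IL-12, IL-17, IL-22, IL-23,
  IFNγ, GM-CSF.
* **Clinical markers**: serum C-reactive protein (CRP, mg/L) and fecal
  calprotectin (FCP, mg/kg stool).

Wiring (see `ibdqsp.network.build_network` for the authoritative list):

* IL-12 drives Th0→Th1 differentiation and NK1 expansion; Th1 and NK1
  produce IFNγ.
* IL-23 and IL-6 drive Th0→Th17; Th17 produces IL-17 and IL-22; a constant
  basal term provides an IL-23-independent IL-17 source. Treg inhibits both
  differentiation arrows. The naive pool is homeostatic — differentiation
  reads Th0 but does not deplete it, so blocking one branch cannot boost
  the other.
* TNFα activates iDC→eDC, M0→M1 and Neu→Neu_a; IL-6 co-activates dendritic
  cells, IFNγ co-activates macrophages, IL-17 co-activates neutrophils.
  These latter two edges carry the IL-12p40 axis into the innate
  compartment: without them, anti-IL-12/23 therapy could not move CRP or
  FCP at all, contradicting the clinical picture.
* eDC, M1 and Neu_a (half-weighted) produce TNFα, IL-6, IL-8 and GM-CSF;
  eDC and M1 produce IL-12 and IL-23. IL-6 production is additionally
  modulated by TNFα through a Michaelis–Menten factor with half-maximum
  `Km_TNF_IL6` and a TNFα-independent floor `b_IL6_TNF` (10%).
* CRP is produced under saturating IL-6 drive (`Km_IL6_CRP`, plus a small
  basal floor `b_CRP`) and cleared with a ~19 h half-life. FCP is driven by
  activated neutrophils and IL-8 with slower washout (0.5/day).

All modifier arrows are Michaelis–Menten (global Hill coefficient 1,
configurable in [1, 4]); every species has first-order turnover; production
terms carry small basal floors. Rate laws exist twice: a fast closed-form
right-hand side and an interpretive evaluation of the declarative reaction
table; the test suite holds them equal to 1e-10 on random states.

### Nominal parameters

The upstream training of such a network against literature steady-state
data is not reproducible here, so the nominal parameter set is *designed*:
turnover rates, half-maximum constants, basal fractions and pathway weights
are fixed at physiologically sensible values, a typical active-disease
steady state is declared (CRP 10 mg/L, FCP 600 mg/kg, TNFα 15 pg/mL, IL-6
8 pg/mL, ...), and the influx/production gains are solved in closed form so
that state is an exact equilibrium (`ibdqsp.params.nominal_parameters`).
The free design constants were then set, once, so that the *calibrated*
model reproduces the reported qualitative drug behaviours: a large CRP/FCP
decrease under TNFα blockade, a minor CRP change under IL-12p40 blockade,
deep CRP suppression under IL-6 blockade, and combination therapy driving
the population median CRP below 3 mg/L and FCP below 250 mg/kg. This
design-for-reported-behaviour replaces the original model training, which
is out of scope here.

Numerical settings: time unit days; LSODA with rtol 1e-8 / atol 1e-10 for
trajectories (steady-state relaxation uses 1e-6 before a Newton polish and
a 1e-8 scaled-residual check); integrations restart at dose times, where
the forcing is discontinuous. States are clamped at zero inside saturating
terms, which keeps trajectories non-negative to solver tolerance.

## Pharmacokinetics and drug binding

Each antibody follows linear two-compartment kinetics with closed-form
biexponential (IV bolus) or triexponential (first-order SC absorption)
solutions, superposed over dose events; mg/kg doses resolve at a fixed
70 kg body weight. Per-drug parameters are repository defaults in the range
typical of therapeutic IgG mAbs (CL 0.25–0.30 L/day, V1 3–3.5 L, V2
2.5–3 L, Q 0.4–0.6 L/day, ka 0.25/day, F 0.7), overridable from
configuration; the source publications' exact values are cited but not
printed in the trial reports this package works from. Every subject in an
arm shares the arm's concentration profile: between-patient variability is
purely pharmacodynamic by construction.

Drug effect enters through quasi-equilibrium binding: with total cytokine
T, binding sites B = 2 × drug (nM), the free cytokine L solves
L² + (Kd + B − T)L − KdT = 0 (cancellation-safe conjugate form), and the
free *fraction* L/T multiplies the cytokine's concentration in every rate
law it modifies. Dynamic on/off binding is deliberately omitted: antibody
binding equilibrates within minutes against weekly dosing. Default
affinity is 0.1 nM for all five drugs (ustekinumab → IL-12+IL-23;
brazikumab, risankizumab → IL-23; infliximab → TNFα; PF-04236921 → IL-6);
two drugs sharing a target would combine multiplicatively.

## Virtual populations

A plausible-patient database is sampled by drawing log-uniform ±10-fold
multiplicative factors on 15 variability parameters — TNFα turnover
(`kdeg_TNF`), the TNFα→IL-6 half-maximum (`Km_TNF_IL6`), the CRP, FCP,
IL-6, IL-8, TNFα, IL-17, IL-12 and IL-23 production gains, neutrophil
influx and activation, DC activation, and the two T-differentiation rates —
re-solving each candidate's steady state, and keeping those with baseline
CRP in [0.1, 200] mg/L, FCP in [10, 5000] mg/kg and all cytokines below
10⁴ pg/mL (acceptance below 1% aborts with a prior-misspecification
error). The hepatic CRP response curve itself (Km, floor, half-life) is
held common across patients: inter-subject variability lives in the
inflammatory drive, not in the readout, which keeps absolute CRP
normalisation a meaningful endpoint across the population.

Trial populations are selected from the database to match a trial's
*reported* baseline summaries — median+IQR, mean+SD, or median+range, since
reporting styles differ between studies — by importance-weighted sampling
without replacement toward the target lognormal marginals of log-CRP and
log-FCP (weights: target density over a kernel estimate of the cohort's
own density, annealed over a small temperature schedule), followed by an
accept/reject check on the achieved joint statistics. Central statistics
must match within the stated relative tolerance (default 15%); dispersion
scales within 3× that (5× for ranges, which are extreme-value statistics).
The CRP–FCP correlation is left as the mechanism induces it. Failure after
the iteration cap reports the best achieved statistics.

## Trial simulation and responder analysis

Arms are simulated patient-by-patient from each subject's own steady state
under the arm's shared free-fraction forcing, on a daily grid over an
84-day induction horizon. Placebo arms carry no drug and stay flat — the
framework models treatment effect only, and printed placebo rates are
removed arithmetically (`placebo_corrected`). Summary curves of every
reported kind are recomputable from the persisted per-patient series.

Responder criteria follow the published cutoff cases: ≥60% CRP decrease at
week 6 (the text's ≥ is used where the figure caption says >; the
comparison is configurable), and absolute normalisation below 3 mg/L CRP,
5 mg/L CRP, or 250 mg/kg FCP, excluding patients already below the cutoff
at baseline. Week 6 means day 42, assessed at the nearest grid point
(error if none within half a day). Partitions (both / only-A / only-B /
neither) conserve the included population exactly.

Known divergence: with this parameterisation essentially no virtual
patient responds to ustekinumab alone at the 60% CRP criterion, whereas
clinical experience with anti-IL-12p40 therapy implies such a group. The
directional findings (infliximab-only responders have higher baseline TNFα
and CRP and lower `kdeg_TNF`/`Km_TNF_IL6`; combination dominates both
monotherapies patient-by-patient) are reproduced and tested.

## Calibration

`CrohnsQSPModel.fit` adjusts a small named subset of nominal parameters
(and optionally a drug affinity, addressed `"Kd:<drug>"`) so simulated arms
reproduce printed clinical outcomes. The default target set is the most
direct published readout of the CRP axis: the week-12 median percent CRP
reductions of the anti-IL-6 (PF-04236921) 10/50/200 mg SC induction arms
(65.6%, 86.3%, 95%). The objective is a weighted sum of squared relative
residuals (log-scale for absolute concentrations, per-100 for percent
changes) over a surrogate population whose membership and steady-state
warm starts are frozen at problem construction, making the loss a pure
deterministic function of the parameters; stored residuals are
reproducible to 1e-10 by re-simulation. Optimisation is log-space
Nelder-Mead with optional seeded multistart, bounded ±100-fold by a
quadratic penalty.

The default search is deliberately two-dimensional — the anti-IL-6 Kd
(which sets the dose separation through the washed-out drug concentration
at week 12) and the basal CRP floor `b_CRP` (which caps maximal
suppression). Wider searches including `Km_IL6_CRP` proved degenerate:
the optimiser saturated the IL-6→CRP arrow to fit the surrogate medians
while generalising poorly to the full population. Parameter recovery on
synthetic targets (3-fold perturbations, 20 seeded repeats, 25% tolerance
on the identifiable parameters) is the module's core validation.

Problem sizes: calibration runs on a ~60-patient surrogate drawn by
striding the matched population, reported results on 200-patient matched
populations from a 600-patient database; the test suite uses smaller
editions of the same pipeline. These sizes were chosen as the desk-scale
working point of the package.

## Synthetic trial reports

All clinical inputs are *summary statistics*; no patient-level data exist
anywhere in the workflow. `ibdqsp.synthetic` fabricates trial reports with
known ground truth — lognormal baseline laws (defaults: CRP median
10 mg/L, FCP median 600 mg/kg, geometric SD 2.5, bracketing the baselines
reported across CD induction trials) summarised in each trial's preferred
style, and longitudinal summaries following a prescribed suppression curve
plus seeded noise — so selection, simulation, classification and
calibration run end-to-end with no download. What the generator does *not*
emulate: reporting biases, dropout, placebo response, covariate structure
(age, weight, disease location), or PK variability; tests passing on these
fixtures demonstrate the machinery and the model's internal consistency,
not fidelity to any real trial population. It also encodes the five
printed induction regimens and the four published responder cutoffs
(`make_paper_defaults`), marked as synthetic defaults.

## Limitations

* Single-compartment biology: no epithelial barrier, lumen transport,
  disease-location effects, membrane TNFα/receptor-level signalling, IL-6
  trans-signalling, or Th2 arm. FCP is a serum-equivalent readout.
* Linear PK only; no target-mediated disposition, immunogenicity or ADA.
* No placebo-response or trial-design model; no clinical-score (CDAI)
  linkage.
* Treg and NK1 carry minimal wiring (homeostatic / IL-12-driven) and only
  feed differentiation inhibition and IFNγ production respectively.
* The nominal parameterisation is a declared design, not an inference from
  data; quantitative responder partitions inherit that caveat.
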