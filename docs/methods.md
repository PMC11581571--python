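# Methods

This note documents the model implemented by `psmapet`: its structure,
parameter handling, numerical conventions, the synthetic inputs it generates,
and the design choices made where the published description leaves the design
open.

## Model structure

**Decision tree.** A cohort of patients imaged at biochemical recurrence is
allocated by true disease status and test result. Writing *d* for the
probability of PSMA-PET-detectable disease (0.752) and *m* for the metastatic
fraction among detected disease (0.8139):

- *Upfront PSMA-PET* is the criterion standard: mass 1−d is truly
  disease-free and read as such; d(1−m) localized and dm metastatic, all
  correctly classified.
- *Reflex PSMA-PET* detects every truly diseased patient (either CTBS finds
  them or the reflex PSMA-PET does). Disease-free patients test CTBS-positive
  with probability 1 − specificity; these false positives are classified
  localized vs metastatic **in proportion to the true disease mix**
  (1−m : m). This rule is the unique simple choice that reconciles the
  reflex strategy's published detection row with the published inputs.
- *CTBS alone* detects truly diseased patients with sensitivity 0.38
  (classified by true state); the remainder enter false-negative (FN)
  compartments. False positives arise as in the reflex strategy.

Detected masses are multiplied through management (Dirichlet) splits:
no-treatment / radiation / systemic for apparent no-disease, no-treatment /
local / systemic for localized (with a recorded prostatectomy / radiation /
cryotherapy sub-split that does not change the health state), and systemic
(ADT + ARSI) vs metastasis-directed therapy (MDT) for metastatic disease.
FN compartments receive no management until identified.

The *reporting surface* (detection and treatment-initiation tables) uses
apparent, as-imaged categories: under CTBS alone, missed disease is counted
as "no radiographic disease" and shares that category's management mix. The
Markov engine, by contrast, tracks FN patients in their own compartments.

**Markov model.** Annual cycles from age 66 to 110. States: no radiographic
disease (three management profiles), localized disease (three profiles),
no radiographic disease after localized (reachable only from localized with
local treatment), metastatic (ADT+ARSI or MDT), mCRPC, death from prostate
cancer, death from other causes, FN-localized and FN-metastatic, and
false-positive profiles (disease-free patients carrying a localized or
metastatic management label). Annual transition probabilities are the
published ones; hazard ratios act through the constant-hazard conversion
p → 1 − (1−p)^HR. FN compartments progress with HR 1.79 applied to the
untreated base probability of their true state and are correctly identified
with probability 0.10 per year, entering the detected states with the
standard management splits and losing the penalty thereafter. Only mCRPC
leads to prostate-cancer death (annual probability 0.3486, the exponential
conversion of a 19.4-month median overall survival).

**False positives.** FP patients keep the *transition dynamics of their true
state* (no radiographic disease) while occupying the utility and management
profile of the assigned state. Consequence: the upfront and reflex
strategies have identical life-years and deaths at the point estimates and
differ only in QALYs (FPs bear the disutility of unnecessary treatment).
The source study's long-term table suggests its authors instead gave FP
patients the assigned state's dynamics; we regard the true-state convention
as the defensible one (a disease-free patient does not acquire metastatic
biology by mislabelling) and note the divergence.

**Utilities.** Utility attaches to the underlying health state, detected or
not: FN-localized uses the untreated-localized utility (0.90) and
FN-metastatic the metastatic-disease utility (0.80, the only metastatic
utility published). FP profiles use the assigned state's utility. Death
states have utility zero.

**Competing mortality.** The age-specific all-cause probability q(age) is
applied to every alive state first; disease transitions are scaled by
1 − q(age) (standard cohort-model convention). The final cycle applies the
life table's closure row (q = 1 at age 110), so the lifetime horizon leaves
the cohort fully absorbed.

**Accrual.** Life-years accrue for alive states and QALYs weight occupancy
by state utility, both discounted at 1/(1+r)^cycle with r = 0.03 (the
published discount rate); death counts are undiscounted. No half-cycle
correction is applied by default (the source describes none); a
`half_cycle` flag provides the trapezoid variant. We note that the source's
printed life-year magnitudes are closer to undiscounted accrual under our
life table (11 259 vs printed 10 987 per 1000 for upfront PSMA-PET;
discounted accrual gives 9 153); discounting nevertheless defaults to on,
following the printed 3% input, and is exposed as a setting.

## Parameters and uncertainty

Each input row carries a point estimate, a 95% uncertainty interval and a
family:

- **Beta** rows pin the mean to the point (it drives the deterministic run)
  and fit the concentration α+β by least squares on the printed
  2.5th/97.5th percentiles (bounded scalar minimisation over log10(α+β)).
  For almost all rows the fitted quantiles recover the printed bounds within
  0.01. Three rows cannot reach that agreement with the mean pinned: the two
  utility rows whose point was deliberately adjusted downward for short-term
  salvage-therapy toxicity, 0.83 (0.81–0.88) and 0.83 (0.78–0.98) — the
  printed interval midpoint lies above the printed mean, which no Beta with
  that mean can reproduce — and, marginally, CTBS specificity 0.91
  (0.85–0.97), where the least-squares optimum misses the upper bound by
  0.011 because of the skew of a Beta with mean 0.91.
- **Dirichlet** groups pin the mean composition and fit one effective-sample
  -size concentration per group against all members' printed marginal
  intervals (each marginal of Dirichlet(pν) is Beta(p_iν, (1−p_i)ν)).
  Complementary pairs printed as Beta (detection/no-disease,
  localized/metastatic given detected, systemic/MDT) are encoded as
  two-component groups so every draw sums to exactly one.
- **Log-normal** rows (hazard ratios) treat the point as the median
  (μ = ln point) and set σ = ln(UI_high/UI_low)/(2·1.96), the least-squares
  solution in log space. The early-vs-delayed HR 0.56 and the FN HR 1.79 are
  reciprocal encodings of one effect; the engine consumes only the 1.79
  form (applying both would double-count).
- **Fixed** rows (median age 66; discount rate 3%; the 10%/year FN
  identification rate, for which no distribution is published) are constant
  in the probabilistic analysis.

Percentages are converted to proportions once at load. The probabilistic
analysis draws 10,000 parameter sets by default; every sampling unit has its
own deterministic stream keyed by (seed, unit index), so draw *i* of any
parameter is independent of the batch size. The same draw feeds all three
strategies within an iteration (common random numbers), which is what makes
the strategy-difference intervals much tighter than the marginal ones.
Draws whose implied transition rows would exceed probability one are
resampled and logged (essentially never triggered at the published values).
Summaries are arithmetic means with empirical 2.5th/97.5th percentile
intervals (linear interpolation).

## Synthetic inputs

Two inputs the analysis needs are not published and are generated:

- **Background mortality**: Gompertz hazard
  q(age) = 1 − exp(−a·e^{b(age−66)}) with slope b = 0.09/year (a typical
  adult-mortality doubling time of ~8 years) and level a calibrated by
  root-finding so the period life expectancy at 66 is 17.0 years, in the
  plausible range for US males at that age. The table is regenerable
  (`psmapet fixtures`) and replaceable by any CSV with `age,qx` columns.
  Long-term outcome *magnitudes* (not the detection columns, and not the
  qualitative orderings) depend on this choice; tests therefore check
  analytic properties, orderings and signs rather than absolute life-year
  values.
- **Institutional cohort**: per-patient PSA level (log-uniform within the
  a-priori strata 0–1.99 / 2.00–4.99 / ≥5.00 ng/mL, default mix
  0.52/0.33/0.15 chosen so the median PSA is ~1.8 ng/mL, the observed
  value), imaging finding, and management category. Stratum-specific
  detection and metastatic-fraction probabilities are logit-shifted
  monotonically in PSA with a common offset solved so the mix-weighted
  average reproduces the overall point exactly. Registry re-estimation from
  a generated cohort (event counts + 1 smoothing for Beta rows, category
  counts + 1 for Dirichlet rows) closes the counts → parameters loop and is
  tested to recover every cohort-informed probability within 0.03 at
  n = 10,000. The generator emulates aggregate frequencies only — it has no
  PSA kinetics, no correlation between PSA and management given the finding,
  and no reader variability — so passing tests validate the
  distribution-fitting path, not clinical realism of individual records.

## Scenario engines

- FN-progression HR sweep over 0.75–2.50 (harm through benefit; 9 points by
  default), patching only that row;
- MDT HR sweep over 0.125–1.000 (no benefit at 1);
- CTBS accuracy grid, sensitivity 0.15–0.65 × specificity 0.40–1.00;
- PSA strata, patching only the imaging-finding parameters (detection and
  metastatic fraction) from the synthetic generator's monotone adjustments
  while holding all other inputs at base values. Because the true
  stratum-specific inputs are unpublished, stratum outcomes are meaningful
  as orderings (deaths increase with PSA stratum for every strategy;
  benefit positive in every stratum), not as absolute values.

## Known limitations

- Single imaging event; no sequential imaging, no equivocal reads, no reader
  variability, no costs (all outside the model's scope).
- Cohort-level Markov structure: no patient heterogeneity or time-dependent
  risks beyond age-dependent background mortality.
- Long-term absolute magnitudes are conditional on the synthetic life table;
  the strategy orderings and the detection/treatment columns are not.
- The published long-term table cannot be matched cell-for-cell: it depends
  on that unpublished life table and on the false-positive dynamics
  convention noted above. At base case this implementation yields
  strategy-1-vs-3 differences of +695 life-years, +539 QALYs and −53
  prostate-cancer deaths per 1000 (discounted; +952 life-years
  undiscounted), versus the published +988 / +824 / −75.
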