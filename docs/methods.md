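# Methods

`chondrosim` is a patient-level, continuous-time discrete-event simulation
(DES) of the lifetime treatment pathway after a symptomatic articular
cartilage defect of the knee, built to compare two healthcare scenarios from
the perspective of the German statutory health insurance (SHI):

* **with M-ACI** — matrix-associated autologous chondrocyte implantation is
  available and used as the primary repair in every patient;
* **without M-ACI** — the counterfactual world in which the same patients
  are managed with microfracture (MF), matrix-associated bone marrow
  stimulation (mBMS), partial or total knee replacement (PKR/TKR) and
  conservative care.

Each patient is simulated once in both scenarios (a paired design), from
model entry (first presentation with a symptomatic defect) until death.
Outcomes are lifetime quality-adjusted life years (QALYs), lifetime direct
costs (EUR), their discounted counterparts, the incremental
cost-effectiveness ratio (ICER), the cost-effectiveness acceptability curve
(CEAC), and pathway statistics such as lifetime TKR incidence.

## Synthetic cohort

The original study population (10,000 M-ACI recipients; manufacturer
production data) is proprietary, so the `population` module generates a
distribution-matched synthetic cohort instead. Only the published marginals
are reproduced: the sex split (60.7% male), per-sex age strata (<35,
35–45, 45–55, ≥55 years) and defect-size strata (<2 to ≥10 cm²), and the
per-sex means (age 35.9/36.6 yr; defect 4.5/4.1 cm²). Sampling is
stratified-uniform within bands, followed by a per-sex shift-only
mean-matching step with values clipped to their stratum (so band occupancy
is preserved exactly while the sample mean hits the published target within
1%). Age and defect size are treated as independent given sex — only
marginals are published, so any joint structure would be invented. Open
bands are closed at 70 yr and 15 cm²; the smallest defect band starts at
0.5 cm². Clipping piles a small amount of probability mass exactly at band
edges (for example at 2.0 cm², the microfracture eligibility bound); this
is a known, accepted artifact of shift-only matching.

Mortality uses a per-sex life table q(sex, age). The packaged default is a
Gompertz–Makeham hazard h(x) = a + b·e^{g·x} (male a=3e-4, b=6.8e-6,
g=0.112; female a=2e-4, b=3.2e-6, g=0.117; maximum age 110), calibrated
once so the baseline cohort reaches a median death age of ≈84.5 years and a
median modelled horizon of ≈47 years, with female life expectancy above
male. Any official table can be supplied as a CSV (`sex,age,qx`). Death
ages are drawn by inverting the piecewise-linear lifetime CDF (death is
uniform within its year), one uniform per patient.

## Failure-time models

Implant/repair durability is a two-component Weibull mixture per
intervention,

    S(t) = w·exp(−(t/λ_s)^{k_s}) + (1−w)·exp(−(t/λ_l)^{k_l}),

a short-term component for early failure and a long-term wear-out
component. Calibration is anchor-based: the long-term component is fitted
through configured survivorship anchors (exact closed form through two
points, k = ln(ln S₁/ln S₂)/ln(t₁/t₂); least squares on the log–log
linearised survival for more; a fixed shape for a single anchor), then the
short-term scale is solved so the *mixture* reproduces the published
2-year failure probability exactly (7% M-ACI, 39% MF, 4% mBMS/PKR/TKR).
Sampling draws a component by w and inverts that component's CDF; two
uniforms per draw, so paired runs stay in lockstep.

The 2-year rates are published; the long-term anchors and mixture weights
are **calibration inputs** (the original estimates are not public). They
were fixed, once, so the simulated pathway statistics reproduce the
reference cohort's reported behaviour: ~82%/86% of patients reach a second
intervention, ≈47%/77% have had one by 25 years (with/without M-ACI),
2.2/3.2 surgeries per lifetime, and a TKR service life with median
revision-triggering failure inside 20–30 years. Defaults: M-ACI long
anchors S(25)=0.88, S(40)=0.15 at w=0.5; MF S(10)=0.55, S(25)=0.20 at
w=0.5 (the 39% early failures in the short component, survivors durable);
mBMS S(10)=0.55, S(25)=0.05 at w=0.15; PKR S(15)=0.85, S(25)=0.30 and TKR
S(15)=0.97, S(25)=0.56 at w=0.10.

## Event loop and assignment policy

Each trajectory alternates: treatment selection → intervention → a
time-to-failure draw → symptomatic relapse (the defect reverts to its
original size; a `resample` option exists) → re-presentation after a fixed
0.25-year scheduling delay. All-cause death truncates everything; TKR and
revision carry an instantaneous perioperative mortality linearly
interpolated in age between 0.0449% (age 55) and 0.11% (age 80).

Primary assignment follows the published eligibility bands: MF for defects
≤2 cm² (≤5 cm² in the widened-indication scenario analysis), mBMS ≤5 cm²,
M-ACI >2 cm² (and used in all patients in the with-M-ACI scenario, mirroring
the source population), PKR/TKR >10 cm², TKR only at ages 55–80. Defects of
5–10 cm² have no published surgical option; the policy splits them between
extended-indication mBMS and PKR (default 65% PKR in the counterfactual
scenario, 10% in the M-ACI scenario).

Strict eligibility alone cannot produce the reported arthroplasty uptake
(only 3.8% of defects exceed 10 cm², yet 26.4% of counterfactual patients
eventually receive a TKR), so repeatedly operated knees are treated as
degeneration-prone, through three policy channels whose probabilities are
scenario-specific calibration inputs:

* at re-interventions, TKR (age-gated) and PKR are offered with fixed
  per-presentation probabilities, alongside renewed repair;
* from the third intervention onward a patient may exhaust repair options
  and move to a pre-arthroplasty waiting state (utility 0.62,
  conservative-care cost), converting to TKR with an annual probability
  while inside the age window, or to a terminal no-further-repair state
  beyond it;
* a failed PKR converts to TKR (probability 0.4 per presentation when
  age-eligible); a failed TKR receives at most one revision, after which
  the patient remains in a no-further-KR state.

The counterfactual scenario is calibrated to the reported intervention mix
(roughly a quarter MF, more than a third mBMS, the rest PKR-type
procedures; ~13% TKR share at second interventions), the M-ACI scenario to
renewed M-ACI in about a third of re-interventions and a ~4% TKR share.

## Randomness and pairing

All draws come from counter-based substreams keyed by (root seed, patient
id, stream id): adding patients never perturbs earlier patients, and
identical seeds give bit-identical runs. Death age and the primary
intervention's failure quantile are shared between the two scenarios of a
paired run; later failure quantiles, treatment-selection and perioperative
draws are scenario-specific (the decision sequences differ). Fully shared
failure streams were evaluated and rejected: they correlate the scenarios'
cost streams so strongly that the per-patient dominance fraction is
structurally capped far below its observed level, while the paired design
retains the variance-reduction that matters (per-seed TKR incidence with
M-ACI never exceeds the incidence without it, for every seed tested).

## Economics

Utilities are annual weights per health state with year-within-state bands:
symptomatic pre-repair 0.65; post-ACI 0.76 in year 1 then 0.82; post-MF
0.76 / 0.82 (years 2–4) / 0.65 from year 5 until the next event; no further
repair 0.69; awaiting a first KR 0.62; post-KR 0.78; awaiting a second KR
0.56; no further KR 0.69. mBMS uses the MF schedule by default — it is a
marrow-stimulation technique, and on the ACI schedule the counterfactual
scenario cannot lose the reported ~1.3 discounted QALYs (a config switch
`mbms_utility: aci` restores the alternative reading).

Costs: M-ACI 11,000 €, mBMS 3,500 €, MF 500 € (the published cost list also
carries a DRG-based 1,500 €, available as a switch; 500 € is the default
because it reproduces the widened-MF scenario result), PKR 6,000 €, TKR
9,000 €, TKR revision 15,000 €; conservative therapy 800 €/yr during
symptomatic states (pre-repair, pre-KR waits, and the terminal
no-further-care states).

Discounting (default 2%/yr, 4.5% in a scenario analysis): point costs at
event times are discounted continuously, (1+r)^{−t}; continuous streams
(QALYs, conservative therapy) are discounted in annual slices at the
slice-start factor, computed exactly via a prefix-sum table. The ICER is
the ratio of incremental discounted means; the CEAC reports, for each
willingness-to-pay λ, the fraction of patients with incremental net
monetary benefit λ·ΔQALY − Δcost ≥ 0; dominance is Δcost < 0 and
ΔQALY > 0 per patient.

## Sensitivity analyses

The tornado analysis perturbs each published scalar input (six procedure
costs, five 2-year failure rates, the conservative-therapy rate, and a
single multiplier on all utility weights, capped at 1) by ±20% around
baseline, reruns both scenarios with the identical seed and cohort, and
ranks parameters by ICER swing. Named scenario analyses rerun the study
with the discount rate at 4.5%, and with MF eligibility widened to 5 cm² in
both scenarios.

## Problem sizes and reproducibility

The default study is 10,000 patients per run. The acceptance script
averages 30 seeded replicates of the full 10,000-patient study (plus the
two scenario arms; the 4.5% arm re-accrues the same trajectories); a full
run takes a few minutes on one core. The test suite exercises the same
code on full-size runs with three seeds for the stochastic reproduction
checks and on smaller cohorts (250–500 patients) for structural and
property tests. The tornado driver uses 4,000-patient arms.

## What the synthetic data do and do not show

The generator reproduces published marginals, not the real joint
distribution of sex, age and defect size, and the packaged life table is a
smooth parametric stand-in for official period tables. Failure anchors
beyond 2 years and all policy probabilities are calibrated to reported
aggregate pathway statistics rather than estimated from patient-level data;
agreement on the headline outcomes therefore demonstrates internal
consistency of the model chain, not independent clinical validity. Two
dispersion-driven quantities (the CEAC level at 20,000 €/QALY and the
per-patient dominance fraction) come out a few points below the reference
values under every draw-correlation scheme tried: the per-patient spread of
lifetime QALY differences implied by Weibull-mixture churn over ~48-year
horizons exceeds what those reference values imply. They are reported as
computed.

## Known limitations

* No modelling of newly emerging defects at other sites, bilateral knees,
  waiting-list dynamics or capacity constraints.
* Failure hazards are independent of age, sex and defect size.
* The assignment-policy probabilities are scenario-specific constants, not
  clinical decision rules; they are calibration devices.
* SHI perspective only: no productivity losses, work disability or
  rehabilitation funding.
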