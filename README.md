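# sicisim

Simulation and test–retest reliability analysis of the two automated
paired-pulse TMS protocols for short-interval intracortical inhibition
(SICI): parallel threshold-tracking SICI (**T-SICI**) and automated
conventional amplitude-ratio SICI (**A-SICI**).

SICI — the suppression of a motor evoked potential (MEP) by a subthreshold
conditioning stimulus delivered 1–7 ms earlier — is a candidate biomarker
for disorders of cortical inhibition such as ALS. Whether it can support
individual-level clinical decisions hinges on its test–retest reliability,
which is hard to study systematically in humans: the ground truth of a
subject's inhibition is unobservable. `sicisim` provides that ground truth.
It simulates virtual subjects with known recruitment curves and inhibition
profiles, runs both acquisition protocols on them sweep by sweep (adaptive
threshold tracking, pseudorandomised scheduling, EMG-contamination gating),
and feeds the resulting examinations through the complete reliability
battery — so that estimator bias, protocol behaviour and the reliability
statistics themselves can all be validated against known truth.

## Model

A virtual subject's noise-free recruitment curve is semi-logarithmic,

```
log10 MEP(s) = log10(0.2) + b · (s − Δ − θ)      (linear for 0.02–2 mV)
```

with stimulus intensity `s` in % of maximum stimulator output (%MSO),
resting motor threshold `θ` (RMT_0.2mV, the intensity evoking 0.2 mV),
recruitment slope `b` and conditioned threshold shift `Δ` (%MSO, a
rightward shift for inhibition). Trial-to-trial variability is log-normal
(SD `σ` in log10 units); the curve saturates smoothly outside the
log-linear window. The two readouts follow from the same curve:

- **T-SICI** = (conditioned threshold − RMT)/RMT × 100 (% RMT; positive =
  inhibition), with thresholds estimated by weighted semi-log regression
  over tracked sweeps;
- **A-SICI** = 100 · geomean(conditioned MEP)/geomean(control MEP)
  (% of control; below 100 = inhibition), at fixed intensities
  (CS = 70% RMT, TS = TS_1mV).

which makes the two methods log-linearly related:
`log10(A-SICI/100) = −b · Δ`.

Reliability is quantified exactly as in standard agreement methodology:
within-subject SD `σw`, coefficient of repeatability `CR = 1.96·√2·σw`
(back-transformed to a fold-change for log-scaled A-SICI), ICC(2,1) with
F-based confidence bounds and poor/moderate/good/excellent bands,
repeated-measures ANOVA with Mauchly's test and Greenhouse–Geisser
correction, Bland–Altman limits, and the inter-method regression of T-SICI
on log10 A-SICI.

## Worked example

Simulate a small six-subject study (each subject: 2 days × 2 sessions ×
2 examinations per protocol, plus one second-observer session) and print
the group SICI-vs-ISI curves:

```sh
sicisim demo --seed 0 --out demo_out
```

```
 isi  t_sici_mean  t_sici_sem      t_p  a_sici_gmean      a_p  method_r
 1.0     2.230266    2.190304 0.355274     70.014954 0.020752 -0.432416
 1.5     5.238379    1.904932 0.040315     66.687677 0.031094 -0.504868
 2.0     5.484325    1.435672 0.012373     69.346849 0.059440 -0.854986
 2.5     5.621893    1.348589 0.008750     66.898752 0.014546 -0.369488
 3.0     1.867736    1.965998 0.385729     84.465036 0.230215 -0.827644
 3.5     2.363852    1.088530 0.081977     81.015725 0.017877 -0.544783
 4.0     0.308181    2.011444 0.884221     90.041739 0.186620 -0.887436
 5.0    -0.240924    0.966087 0.812987    104.394049 0.353979 -0.725238
 7.0    -1.097566    0.856446 0.256216     99.585704 0.954361 -0.544536
```

Each row is one interstimulus interval. `t_sici_mean` is the group mean
T-SICI (% RMT; positive = inhibition) with its SEM and one-sample p value
against 0; `a_sici_gmean` is the geometric group mean A-SICI (% of control;
below 100 = inhibition) tested against 100 on the log scale; `method_r` is
the across-subject correlation between the two readouts at that ISI. Even
with only six subjects the canonical SICI shape emerges — inhibition
peaking at 1–2.5 ms, fading by 4–5 ms; at the full 18-subject design the
inhibition at 1–3 ms and the facilitation at 7 ms are clearly significant.
`demo_out/` contains one trial-log CSV per examination plus
`examinations.csv`, `reliability_report.csv` (CR, ICC, rmANOVA,
interobserver tests per parameter) and `group_curves.csv`.

The same pipeline is scriptable:

```python
from sicisim import CohortParams, ProtocolConfig, StudyDesign, run_study
from sicisim import summarize_reliability, summarize_group_curves

ds = run_study(CohortParams(n_subjects=18, seed=7), StudyDesign(),
               ProtocolConfig(), seed=1)
report = summarize_reliability(ds)       # tidy CR/ICC/rmANOVA table
curves = summarize_group_curves(ds)      # group curves + pooled regression
```

`sicisim simulate --config cfg.yaml --seed N --out DIR` runs a configured
study, and `sicisim analyze --in DIR --out DIR` recomputes all summaries
from previously written trial logs (thresholds are re-derived from the
logged sweeps, not read from the result tables).

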