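# Methods

This note documents the generative model, the protocol emulation, the
statistical battery and the numerical choices behind `sicisim`, and states
what the simulations can and cannot show about real recordings.

## Virtual-subject model

Each subject is an `ExcitabilityModel`: a stochastic mapping from stimulus
intensity (in % of maximum stimulator output, %MSO) to a scalar MEP
amplitude (mV, peak-to-peak).

**Recruitment curve.** The noise-free core is semi-logarithmic,
`log10 MEP = log10(0.2) + b·(s − Δ − θ)`, exactly linear for amplitudes in
the 0.02–2 mV window, reflecting the empirical observation that single-pulse
MEP recruitment is approximately exponential over a ~100-fold range. The
resting threshold θ (RMT_0.2mV) is the intensity at which the noise-free
curve equals 0.2 mV — the midpoint of the log-linear window — exactly.
Outside the window the curve saturates toward a floor (`mep_floor`,
0.005 mV, baseline noise) and a ceiling (`mep_ceiling`, 5 mV) by a C1
exponential approach: identity inside the window, so regressions over
in-window sweeps are never distorted, with no kink at the joins. (A global
sigmoid would be smoother still, but cannot keep the threshold definition
and in-window linearity exact; those invariants anchor the estimator
tests.)

**Conditioning.** A conditioning stimulus at interstimulus interval ISI
shifts the curve along the intensity axis by Δ(ISI), parameterised as a
percentage of θ (positive = inhibition = rightward shift). This single
mechanism generates both readouts consistently: the tracked conditioned
threshold rises by Δ, and the amplitude ratio at fixed test intensity is
`10^(−b·Δ_abs)` — the model-level origin of the log-linear relation between
the two SICI methods.

**Noise structure.**

- Trial-to-trial variability: additive Gaussian noise on log10 amplitude,
  SD `sigma_log` (default 0.2 log10 units ≈ ×/÷1.6), applied after
  clamping.
- Session drift: each examination adds one draw of N(0, `session_drift_sd`)
  to θ (default 1.5 %MSO), representing coil-repositioning and slow
  excitability shifts. It moves the whole curve, so SICI readouts, which
  are internally referenced, are largely insensitive to it; threshold
  repeatability is not.
- Within-subject SICI fluctuation: each examination adds independent
  N(0, `inhibition_sd_within`) (default 2.5 %RMT) per ISI to Δ,
  representing physiological inhibition variability between examinations.
  Without it, simulated SICI test–retest variation collapses to sweep
  noise alone, far below what human test–retest tables report. The two
  defaults were calibrated once against the magnitude of published
  repeatability coefficients (RMT CR ≈ 5–10 %MSO; single-ISI T-SICI CR ≈
  9–17 %RMT) and then frozen.
- Contamination: each sweep is contaminated with probability
  `contamination_rate` (default 0.02); contaminated sweeps carry an
  exponential prestimulus EMG peak (mean `contamination_amp_mv`, 0.03 mV)
  checked against the 0.015 mV gate.

**Cohort distribution** (`CohortParams`). Thresholds are
Normal(55.2, 8.4) %MSO truncated to [20, 95] so that a 120 %RMT test
stimulus stays deliverable; slopes Normal(0.065, 0.012) truncated positive.
The slope default makes TS_1mV ≈ 119–120% of RMT, matching the reported
ratio between the two tracked thresholds. Between-subject inhibition
variability has two parts: a shared per-subject inhibition-strength factor
Normal(1, 0.55) multiplying the whole mean profile, plus independent
per-ISI wiggle N(0, 2) %RMT. The shared factor is essential: it reproduces
subject-level concordance across ISIs (a weakly inhibited subject is weak
everywhere, and a negative draw yields the occasional subject who
facilitates at all ISIs) and keeps group-level facilitation at 7 ms
detectable at n = 18, neither of which a purely independent per-ISI spread
achieves. The default mean profile (% of RMT)
`{1: 10.3, 1.5: 8.0, 2: 7.0, 2.5: 7.5, 3: 5.5, 3.5: 4.0, 4: 2.0, 5: 0.0, 7: −4.0}`
is anchored at published group means for ISIs 1, 2.5 and 3 ms; the
remaining entries are free defaults shaped to the canonical SICI curve
(two inhibition peaks at 1 and 2.5 ms, crossover near 5 ms, facilitation
at 7 ms).

## Threshold tracking and estimation

**Proportional tracking.** The stimulator intensity is corrected by
`−gain · log10(MEP/target)`, clipped to ±`max_step` (2 %MSO for the initial
RMT_0.2mV and TS_1mV estimation, 1 %MSO for in-protocol control channels).
The gain equals `max_step` per log10 unit of error, so a full step is taken
only for a ≥10-fold miss — a choice the protocol description leaves open;
it preserves "maximum step" semantics with a smooth approach and leaves
the intensity unchanged exactly on target.

**Validity and stopping.** An estimate is valid when the MEP lands within
the 20% tracking error on the log axis (|log10(MEP/target)| ≤ log10 1.2)
or when two successive MEPs bracket the target line. Tracking stops at six
valid estimates (counted cumulatively, not consecutively) with a safety cap
of 100 trials; hitting the cap yields an invalid estimate that propagates
as a failed examination — the analysis handles these by listwise deletion,
mirroring subject exclusions in human studies.

**Regression estimator.** The threshold is where the weighted straight-line
fit of log10 MEP on intensity crosses the target amplitude. Sweeps outside
the 0.02–2 mV window and gated sweeps are excluded; zero responses are
recorded at the floor amplitude and fall outside the window. Weighting is
Tukey-biweight IRLS (c = 4.685, MAD scale, 3 iterations, OLS seed), giving
points near the running fit more influence; with exactly collinear data the
OLS fit is returned unchanged. Fewer than two usable sweeps, a non-positive
fitted slope, or a crossing outside [0, 100] %MSO make the estimate
invalid.

## Protocol emulation

Both protocols deliver 9 ISI conditions (1–7 ms) × 10 repetitions plus 30
control stimuli in 10 pseudorandomised cycles of the 12 conditions, at 5 s
per sweep (timestamps only; no real-time pacing is modelled).

**T-SICI.** Nine conditioned channels start at 120% of the incoming RMT
estimate and step 1 %MSO toward the 0.2 mV target; the step doubles to
2 %MSO after two consecutive misses (outside the 20% log tolerance) on the
same side and resets when a sweep lands within tolerance. RMT is tracked
concurrently on three control channels (proportional rule, 1 %MSO maximum
step); the three control slots of each cycle rotate through the channels.
After every cycle the conditioning stimulus is recomputed as 70% of the
mean of the three control-channel regression estimates (falling back to a
channel's current intensity while its regression is not yet valid). At the
end, per-ISI conditioned thresholds and the pooled-control RMT come from
the regression estimator; when the pooled control regression is degenerate
(its tracked intensities can span under 2 %MSO), the pre-examination
tracked RMT is used — the same fallback applies when logs are re-analysed.
T-SICI per ISI is the relative threshold rise; band values (1–3.5 ms,
1–7 ms) are arithmetic means of the member-ISI values.

**A-SICI.** Intensities are frozen for the whole examination (CS = 70% of
the incoming RMT estimate, TS = TS_1mV). Per-ISI A-SICI is the
geometric-mean conditioned/control amplitude ratio; band values pool the
member ISIs' sweeps (geometric-mean ratio over 60 or 90 conditioned
sweeps), not the per-ISI ratios.

**Gating.** A sweep whose prestimulus EMG peak exceeds 0.015 mV is
discarded and redelivered at the end of the current cycle, keeping the
10/30 per-condition counts fixed (total redeliveries capped at twice the
scheduled length). The 15 µV online gate is treated as equivalent to the
prestimulus gate; no waveform-level check exists because no waveforms are
synthesised. Gated sweeps never step a tracker and never enter estimation.

## Study design and summaries

The default design is 2 days × {morning, afternoon} × 2 examinations per
protocol per session by observer 1 (8 intraobserver examinations per
subject per protocol) plus one second-observer examination per protocol in
the afternoon of day 1 (9 total). Every examination independently
re-estimates RMT_0.2mV (and TS_1mV before A-SICI) — the within-session
repeats do not share threshold estimates, which attributes threshold
estimation noise to within-session variance. The observer effect is an
additive per-observer offset on the latent threshold (SD configurable,
default 0, since no systematic observer bias was expected).

Summaries per parameter (SICI at 1, 2.5, 3 ms; bands; RMT; TS_1mV — A-SICI
analysed as log10): CR per session pair; intraday ICC (morning pair,
afternoon pair, first-morning + first-afternoon); interday ICC (first
examination of matching sessions across days); rmANOVA over the eight
examinations; interobserver ICC and paired t test against the first
observer-1 examination of the matching session. Group curves use
arithmetic (T-SICI) or geometric (A-SICI) per-subject means with
one-sample tests against the null readout (0 %RMT / 100% control, the
latter on the log scale), plus per-ISI and pooled inter-method
regressions.

## Statistical battery: numerical choices

- `σw` is the root mean square within subjects from the one-way subjects
  ANOVA; CR = 1.96·√2·σw. The CR 95% CI treats n(k−1)·σw²/σ² as χ² with
  n(k−1) df (the published source for this interval is not explicit about
  the method; the χ² interval is the exact one under normality). On the
  log10 scale CR is reported back-transformed as 10^CR, a fold-change.
- ICC(2,1) is computed from the two-way mean squares with the standard
  F-based confidence bounds (Satterthwaite df for the denominator); bands
  are poor < 0.50 ≤ moderate < 0.75 ≤ good ≤ 0.90 < excellent, with 0.90
  resolved as "good" per the conventional interval notation. Zero total
  variance yields a missing ICC; zero error variance yields ICC with
  degenerate bounds.
- rmANOVA: one within factor (examination). Mauchly's W uses the
  first-order χ² approximation; Greenhouse–Geisser ε is applied to both
  df when Mauchly's p < 0.05 and is clipped to [1/(k−1), 1]. A singular
  repeated-measures covariance (inevitable when subjects ≤ repeats, e.g.
  cohorts of ≤ 8 analysed over 8 examinations) sets ε to its lower bound
  with a warning. Significant omnibus tests are followed by
  Bonferroni-corrected pairwise paired t tests.
- Bland–Altman: bias ± 1.96·SD of the paired differences, back-transformed
  to ratio and fold-limits on the log scale.
- Inter-method regression: OLS of T-SICI on log10 A-SICI, Pearson r with
  Fisher-z CI.
- Missing cells are handled by listwise deletion of subjects, counted on
  the matrix.

All of these are computed definitionally (mean squares from sums of
squares) rather than delegated, so they can be cross-checked in the test
suite against independent implementations (pingouin, scipy) to 1e-8.

## Problem sizes and determinism

The test suite and the acceptance script run the full default study
(18 subjects × 9 examinations × 2 protocols ≈ 75,000 simulated sweeps,
a few seconds on one CPU). Replicate-study properties (band-averaged CR
below single-ISI CR; ICC falling with injected noise) use 16 and 12
replicate studies respectively — enough to resolve the ≥80% and median
comparisons while keeping the suite under two minutes. Monte-Carlo checks
use 100–200 replicates or 10,000 draws. Every stochastic path derives from
explicit seeds: the cohort from `CohortParams.seed`, examinations from
per-examination `SeedSequence` children of the study seed, so single
examinations are reproducible in isolation and reruns are byte-identical.

## What the simulations do and do not show

The generator reproduces the statistical skeleton the analysis assumes:
log-linear recruitment with log-normal sweep noise, an intensity-axis
conditioning shift common to both protocols, between-subject spread of
thresholds and inhibition, session-level drift, physiological SICI
fluctuation, and occasional contamination. Passing tests therefore show
that the acquisition logic and the statistical battery are correct and
unbiased *under this model*, and that the qualitative reliability ordering
(bands more repeatable than single ISIs; thresholds more reliable than
SICI) is a structural consequence of the design.

They do not show that real cortex behaves this way. Not modelled: EMG
waveform shape and latency, coil-position error as a distinct process
(absorbed into `sigma_log` and `session_drift_sd`), intensity-dependent
variance of MEPs, floor effects from unrecordable MEPs, diurnal structure
beyond session labels, stimulator power limits beyond threshold
truncation, and any dependence of Δ on conditioning intensity. Published
human reliability values depend on those unmodelled features and on the
particular cohort; the simulated reliability tables land in the right
range but are not reproductions of them.
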