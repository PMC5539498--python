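# Methods

`attnaccess` re-implements, as a tested pipeline, the analysis chain used
to characterize whether a person can drive a scanning communication board
by modulating mental attention, measured with a single-channel consumer
EEG headset (forehead electrode, ear reference). The sensor emits, once
per second, proprietary attention and meditation indicators (0–100 %), a
vector of power-band values and a contact-quality flag, plus a raw
512 Hz, 12-bit signal. The original recordings were never deposited, so a
synthetic generator stands in for them; everything downstream of the
generator is the analysis a lab would run on real exports.

## Study protocol

Each subject completes 5 sessions of 14 one-minute trials. The first
30 s of a trial is the task half — keep attention **above** 50 % in odd
trials ("attention"), **below** 50 % in even trials ("non-attention") —
and the last 30 s is relaxation, which is recorded but excluded from all
analyses. A full protocol yields 35 task trials per condition.

## Synthetic cohort generator

The generator's contract is the statistical structure the analysis
assumes, not a biophysical EEG model:

* **Attention stream.** A clipped AR(1) process at 1 Hz around a latent
  mean. Defaults: class means `mu_att = 70`, `mu_non = 30` (percent),
  marginal SD `sigma_within = 12`, lag-1 autocorrelation `ar_coeff =
  0.6`. At trial onset the latent mean starts at the *opposite* class
  mean and switches to the trial's class mean after an
  Exponential(`tau_on` / `tau_off`) latency (defaults 2.5 s) — a
  one-parameter stand-in for the empirical switching latencies; any
  unimodal positive latency law would serve. The mean switches when the
  sample's midpoint time `t + 0.5` passes the latency, which makes the
  expected recovered first-crossing time ≈ `tau + 1` s under the 1-based
  second convention (near-unbiased discretization). Values are clipped
  (not reflected) to [0, 100] after each update and the clipped value is
  the carried state, matching a bounded percentage indicator.
* **Band powers.** Log-normal per second (log-SD 0.35) around a 1/f-like
  baseline; attention trials add a per-band log-shift (`band_shift`).
  The demo pattern lowers delta and theta, raises beta and gamma, hence
  lowers theta/beta — the direction pattern expected of attentive states
  on a frontal lead. Default band count is 8 (the sensor's documented
  sub-bands, delta…mid-gamma), configurable to 9.
* **Meditation** is class-independent noise; **contact loss** is
  Bernoulli per second (default 2 %).
* **Raw epochs.** 512-sample integer epochs: *clean* is band-limited
  (0.5–45 Hz) 1/f-shaped noise at SD 30 ADC counts; *blink* adds one
  smooth biphasic deflection (350–650 counts, 300–500 ms); *EMG* adds a
  tapered 60–220 Hz burst (SD 80 counts, 150–350 ms); *motion* adds a
  large slow swing (600–1000 counts) plus broadband noise. The clean
  base is shared across kinds at the same seed, so artifact-vs-clean
  feature comparisons are paired.

What the generator does **not** emulate: volitional strategy changes
across sessions, drifting electrode impedance, the proprietary attention
algorithm itself, or the exact run-length statistics of human attention
(note also that invalid seconds break goal-side runs, so sustained times
computed after artifact screening are deflated relative to clean
streams). Passing tests therefore demonstrate that the *analysis chain*
is correct and
recovers known generative parameters, not that any particular human
population would reach a given accuracy.

## Artifact screen

Non-overlapping 1 s epochs (512 samples) are summarized by two features:
the peak-to-peak range (**MinMax**) and the energy of the residual after
subtracting a Savitzky–Golay smoothed epoch (order 2, window 35;
**ESF**). The smoother is the least-squares local quadratic; mirror
padding handles the epoch edges (the polynomial-reproduction property on
interior samples is the tested contract — the boundary rule is a free
choice). Muscle bursts raise ESF, blinks raise MinMax, motion raises
both. Epochs are labelled by per-label threshold boxes with closed
intervals (deterministic boundary behaviour); boxes are calibrated as
the [q, 1−q] empirical quantiles per label and dimension (default
q = 0.01, conservative: borderline epochs are rejected). A second of the
1 Hz stream is admitted only if the contact flag is 0 **and** its epoch
is clean — detected blinks are still invalid for analysis. Invalid
seconds are flagged, never deleted.

## Trial metrics

All metrics use valid seconds only and a strict threshold (equality
fails the goal). **SS** is the percentage of valid seconds on the goal
side; **t_i** the 1-based second of the first valid goal-side sample;
**t_s** the mean length of maximal runs of consecutive valid goal-side
samples ("mean run" rather than "longest run": the published table pairs
the quantity with small per-trial standard errors, which fits a mean).
Subject summaries pool SS over seconds and average t_i/t_s over trials
with SE = SD/√n. Per-trial features apply the IQR outlier fence
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] (linear-interpolation quartiles) per signal
before averaging: Set1 = mean attention; Set2 adds theta/beta; Set3 =
attention plus all raw bands (10 values at 9 bands; meditation is always
excluded). Theta/beta is the ratio of filtered canonical means
(sub-bands averaged), not a mean of per-second ratios. Note the IQR
fence is not a projection: refiltering an already-filtered sample can
remove further points because the quartiles tighten.

## Band statistics

Per subject, per-trial means (70 rows for a full protocol) are compared
between trial types with the two-sided Mann–Whitney–Wilcoxon test:
exact enumeration when both n ≤ 20 and the pooled data is tie-free,
otherwise the normal approximation with continuity and tie correction
(mid-ranks). Raw p-values are reported for the seven variables
(attention, delta, theta, alpha, beta, gamma, theta/beta) with **no
multiple-testing correction** — these are per-subject descriptive
tables; adjust before making confirmatory claims. Effect directions are
reported only where p < alpha, by comparing class means; exact ties
report none. Survey ratings aggregate to per-subject means across
sessions, then per-group means across subjects (group means of subject
means, which is what the published table prints); exact means are
returned and rounding is left to display.

## Classifier

Two-class LDA with pooled within-class covariance:
`w ∝ (S + λI)⁻¹(μ_att − μ_non)`. λ = 0 unless S is singular or has
condition number > 1e8, in which case λ = 1e-3 · trace(S)/d (when
trace(S) = 0 but the means differ, λ = 1 so the rule degenerates
gracefully to the mean-difference direction; identical means with zero
variance are rejected as inseparable). Priors are equal (balanced
design), so the threshold is the midpoint of the projected class means,
oriented so attention projects higher. Evaluation is stratified 4-fold
CV with a fixed seed: accuracy is pooled correct/total over held-out
folds and AUC is the mid-rank Mann–Whitney statistic of the pooled
held-out scores (pooled rather than fold-averaged: stabler at n = 70).
Note that accuracy decisions are invariant to positive affine feature
maps but *not* to general monotone maps (the midpoint threshold is not
a rank statistic), and pooled AUC picks up fold-specific projection
offsets.

## Access model

Scanning access is feasible when three constraints hold (1.64 is the
one-sided 95 % normal quantile):

1. `t_scan = (t̄_on + 1.64 σ_on) + t_w`
2. `t_w > t̄_off + 1.64 σ_off` (strict)
3. `Np · (N_icons − 1) · t_scan < T_non_att` (strict; `T_non_att` = 30 s)

Latencies t_on/t_off are the 1-based seconds to the first per-second
projection beyond the classifier threshold in attention/non-attention
trials; trials that never cross are excluded from the mean/SD but
counted. `Np(t_w)` is the number of supra-threshold pulses (maximal runs
of consecutive valid seconds) of length ≥ t_w per non-attention trial —
exactly non-increasing in t_w.

Per session and dwell time, 10 random balanced 6/4/4
train/validation/test splits are drawn: training features come from the
first t_w seconds of each training trial; validation/test features come
from a t_w window starting at the first second whose single-sample
projection exceeds the threshold (no IQR filter during the search, IQR
when averaging the chosen window; a trial that never crosses defaults to
non-attention). Validation quantities (accuracy, latencies, Np — pooled
across repeats and sessions) drive the feasibility scan of the integer
grid t_w = 2…15 s (capped at 15 s because the published cohort's mean
sustained time is ≈ 14 s); the first feasible t_w wins and the *test*
trials report its accuracy. If nothing qualifies the subject carries an
infeasible marker. The information transfer rate uses the Wolpaw
formula, `B = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))`,
`ITR = 60·B/t_select` with `t_select = t_w_opt` and N = 2; accuracy at
or below chance clamps to 0.

## Reference tables

`attnaccess.datasets` carries the original study's published summary
cells (six participants: four normally developed, two with cerebral
palsy) so the derived arithmetic is reproducible exactly: best-set group
mean accuracies 82.4 % / 76 %, group-A mean minimal scan period 10.95 s,
one subject's minimal scan period 10.6 s, cohort mean sustained time
≈ 14 s, and survey group means (2.65, 1.5, 2.7). Recomputing the
group-B mean scan period from the printed cells gives 10.22 s, slightly
different from the 10.16 s quoted in the original discussion; the
discrepancy is noted and left unresolved.

## Problem sizes and determinism

Default runs use the full protocol per subject (5 × 14 trials, 1 Hz),
100 + 50 epochs per kind for screen calibration/evaluation, 10 split
repeats per session, and 100-seed / 1000-replicate designs for the
statistical calibration checks — sizes chosen so every property is
measured at useful power while a complete run stays interactive. All
randomness flows from explicit integer seeds (config seed → per-subject
→ per-session streams), and regeneration is bit-identical.
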