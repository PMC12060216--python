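# Methods

This note documents the models, numerical choices and known limitations of
`nirstates`. It is written for users who need to judge what the package's
results — almost all of them demonstrated on simulated cohorts — do and do
not establish.

## Signal model and forward simulation

A recording is 53 channels × 2 wavelengths (690/830 nm) × time at 20 Hz.
The generator builds each subject's oxy-Hb concentration change (µM) as

    oxy(c, t) = Σ_k β(c, k) · r_k(t) + latent(node(c), t)
                + physio(c, t) + drift(c, t) + ε(c, t)

* **Task response.** `r_k` is the unit-peak regressor of condition *k*:
  three contiguous 20 s boxcars convolved with a canonical double-gamma HRF
  (peak 6 s, undershoot 16 s, amplitude ratio 1:6; the gamma shapes are
  `delay + 1` so the positive lobe's mode sits exactly at the stated peak
  delay). The same function builds the GLM design, so with all noise off
  the estimation chain is exact (verified to ~1e-13). β defaults encode the
  study's qualitative pattern: sensorimotor channels (SMA + M1) respond at
  0.8 µM in controls and non-freezers under both conditions; freezers
  respond at 0.25 µM during plain motor imagery and 0.8 µM under auditory
  cueing. Between-subject amplitude scatter is N(0, 0.3² µM) on responsive
  channels; the subject's realised β is the recovery target.
* **Connectivity regimes.** A hidden first-order Markov chain (three
  states, uniform jump distribution, mean dwell 150 s) switches the
  covariance of a latent process living on ten hemispheric region nodes
  (L/R × {SMA, M1, S1, Wernicke, SAC}). The regimes are topographic:
  low = uncoupled (r = 0), medium = sensorimotor block (SMA/M1/S1) at
  r = 0.9 with r = −0.3 motor↔non-motor anticorrelation (the familiar
  task-positive/task-negative opposition), high = globally coupled
  (r = 0.9). Mean strength is strictly increasing, so sorting k-means
  centroids by mean correlation recovers the generating order. Innovations
  are drawn from the active regime's covariance and AR(1)-smoothed with a
  1 s time constant (≈0.16 Hz bandwidth, i.e. the process fills the
  analysis band below the 0.1 Hz low-pass); marginal amplitude 0.1 µM,
  the scale of spontaneous low-frequency oxy-Hb fluctuations.
* **Physiological noise.** Mayer waves (0.08 µM at 0.1 Hz), respiration
  (0.05 µM at 0.3 Hz), cardiac pulsation (0.1 µM at 1.1 Hz), each with
  random per-channel phase; linear drift (±0.1 µM per session); white
  measurement noise (0.3 µM per sample).
* **Deoxy-Hb** is −1/3 of the structured oxy-Hb signal plus independent
  noise; downstream analyses use oxy-Hb only.
* **Optics.** Concentrations map to OD through the modified Beer–Lambert
  law with tabulated extinction coefficients (690 nm: 0.276/2.052; 830 nm:
  0.974/0.693 cm⁻¹ mM⁻¹ for HbO/HbR), DPF 6.0 and 3 cm separation, then
  intensity = baseline·e^(−OD). The preprocessing inverse shares these
  constants, so round trips are exact by construction; all three are
  configurable and recorded in output provenance.
* **Motion artifacts**, in OD units, are global events hitting a random
  half of the channels: Gaussian spikes (amplitude 0.3 × U(0.8, 1.2),
  full width 0.5–2 s, 0.2 per minute) and baseline steps (same amplitude
  law, 0.2 per session). The amplitude law deliberately sits above the
  detector's 0.2 OD excursion threshold: the artifact model exists to
  exercise detection and correction, and events below the detection floor
  would pass through silently by definition of the detector.

## Preprocessing choices

* OD uses the natural log referenced to the channel's temporal mean; the
  resulting per-channel constant is absorbed by the GLM intercept.
* Motion detection flags samples whose windowed (0.5 s) peak-to-peak OD
  excursion exceeds 0.2 OD or 50× the channel's sample-to-sample SD, then
  dilates the mask by ±1 s so artifact tails join the flagged segment.
* Spline correction fits a smoothing spline (csaps-style p = 0.99, mapped
  to the penalty λ = (1−p)/p) inside each flagged segment, subtracts it,
  and rebuilds the series by shifting every segment to connect with its
  predecessor (2 s edge means). Re-leveling is what removes baseline
  steps; its precision is limited by in-band noise over the edge windows
  (~0.001–0.002 OD), which is the dominant residual artifact error.
* The "0.0–0.1 Hz" band is implemented as a zero-phase (forward–backward)
  4th-order Butterworth low-pass at 0.1 Hz; a nonzero low edge switches to
  a true band-pass. Zero-phase filtering keeps event timing intact, and
  because it is linear the GLM applies the identical filter to its task
  regressors, which makes filtering cancel from the estimator.
* Block averages are baseline-referenced to each trial's −5…0 s mean;
  out-of-bounds trials are dropped with a warning.

## GLM and group statistics

OLS per channel with Legendre drift (default order 1) and a constant; an
AR(1) Cochrane–Orcutt option exists but is off by default — the packaged
calibration tests show the OLS p-values are accurate under the generator's
noise, and prewhitening choices would otherwise be invisible assumptions.
Group inference: one-sample t maps, three-group one-way ANOVA with BH-FDR
over the 53 channels (significant channels = ROIs), Fisher LSD post hoc
(pooled within-group MSE, no extra multiplicity correction — that is what
LSD means), and paired t between conditions on each ROI. Summary-statistic
utilities (pooled t, ANOVA F from means/SDs/ns, Pearson χ² without
continuity correction) exactly reproduce raw-data statistics when the
summaries are exact; the packaged demographics table reproduces its printed
statistic column to within the rounding of the printed inputs. The pooled
(not Welch) t is the default precisely because it is the formula that
reproduces the printed values; a Welch variant is provided. A rank-sum
wrapper exists for raw ordinal data only — medians/IQRs do not determine
it, and the table builder marks that row "not computable from summaries".

## Dynamic connectivity states

Node series are hemispheric region means of oxy-Hb **task residuals**: the
fitted task and drift components are removed first, since evoked responses
(~0.8 µM) dwarf spontaneous fluctuations (~0.1 µM) and would otherwise
dominate every window that overlaps a task block ("background
connectivity" practice). The montage's left/right split is synthetic (a
fixed arbitrary halving of each region's channel list, marked as such in
the config) — the true per-channel laterality of this layout is not
published; users with a measured map can supply their own config in the
same format.

Windows are 50 s with a 1 s step (both configurable and logged). The
window length matters: a 0–0.1 Hz signal carries roughly 2·B·T ≈ 10
independent samples per 50 s window, so each pairwise correlation estimate
has a sampling SD of ~0.3 at r = 0. Thirty-second windows (≈6 independent
samples) sit below the stable-estimation floor for this band, which is why
50 s is the default. Correlations are clustered in raw r-space (not
Fisher-z; a z option exists): high-correlation states are tight in r-space
because the estimator's variance shrinks as (1−r²), and centroid "strength"
then reads directly as mean correlation.

K selection uses the elbow criterion — the K maximising the perpendicular
distance of the W(k) curve from the chord joining its endpoints, ties to
the smallest k — computed on **exemplar windows**: per subject/condition
local maxima of the across-pair variance of the correlation vector. With a
1 s step, consecutive windows are nearly identical and windows spanning a
regime switch trace dense bridges between clusters; on all windows those
bridges bias the elbow to K+1. Exemplar subsampling is the standard remedy
in the sliding-window dFC literature. Final clustering is k-means
(k-means++, n_init = 50, fixed seed) on all windows pooled across subjects
and both conditions, so the state space is shared; a subject-level
5-fold cross-validated K selector (`choose_k_crossval`) checks that the
same K reproduces in every fold. State dynamics are summarised per subject
and condition by occurrence probabilities (sum to 1) and the K×K
transition-percentage matrix over consecutive window pairs
(self-transitions included; the matrix sums to 100). Dynamics comparisons
reuse the group-stats machinery: two-sample t between groups within
condition, paired t between conditions within group.

## Graph metrics

Each state centroid becomes a weighted graph on |r| (positive-part and
threshold transforms available). Global efficiency is the mean inverse
weighted shortest-path length (edge length 1/weight, unreachable pairs
contribute 0); clustering is the Onnela geometric-mean triangle intensity
normalised by the network's maximum weight, with degree-<2 nodes
contributing 0. Both are verified against exhaustive path/triangle
enumeration on small graphs, and several weighted generalisations exist —
the Onnela form is documented here because results depend on the choice.

## What the simulations do and do not show

The generator reproduces the statistical structure the analyses assume —
band-limited correlated hemodynamics, HRF-locked responses, Markov regime
switching, detectable motion artifacts — but not real optics (no photon
transport, no scalp/skull partial volume), no superficial systemic
contamination shared between scalp and cortex, no subject motion coupling
between wavelengths beyond a common additive OD term, and no behavioural
variability in task compliance. Passing recovery tests therefore
demonstrates the correctness and calibration of the estimation chain under
its own assumptions, not the validity of those assumptions for any given
device or population. Two quantitative notes:

* Group-mean β recovery on the noisy default cohort sits at the sampling
  floor of the study's group sizes: the latent connectivity noise is
  in-band and shared within regions, leaving a ~1–1.5% standard error on a
  group mean, so the observed 0.5–3% errors are noise, not bias (the
  noiseless chain is exact, and the Monte-Carlo calibration shows unbiased
  β with accurate standard errors).
* State-label recovery is evaluated on windows lying ≥90% within one
  regime; a window straddling a switch has no well-defined true label.
  Elbow and label recovery were validated over 20 seeded replicate cohorts
  at the full study size (55 subjects; ~8,900 windows per cohort).

## Problem sizes used in the packaged checks

Acceptance-style checks run the full default cohort (21/24/10 subjects,
210 s sessions) for β recovery and the study pipeline; 20 replicate
cohorts at full size for state recovery; 10⁴-step chains for dynamics
recovery; and 2,000 null replicates per calibration check. The test
suite's smoke runs use 6-subject cohorts with K fixed at 3, which is too
small for elbow selection but exercises every pipeline stage.
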