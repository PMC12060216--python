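# nirstates

Channel-wise activation mapping and dynamic functional-connectivity state
analysis for block-design fNIRS motor-imagery studies — built around the
question of how rhythmic auditory stimulation (RAS) changes cortical
activity in Parkinson's disease patients with freezing of gait (PD+FOG),
compared with patients without freezing (PD−FOG) and healthy controls (HC).

The package covers the full analysis path for a 53-channel, dual-wavelength
(690/830 nm, 20 Hz) continuous-wave recording of two 60 s imagined-walking
blocks (motor imagery alone, `MI`, and with auditory cueing, `MI+RAS`),
each made of three 20 s trials and flanked by 30 s rests:

1. **Preprocessing** (Homer-style): light intensity → optical density
   (OD = −ln *I*/*Ī*), channel-wise motion-artifact detection and
   smoothing-spline correction with segment re-leveling, zero-phase
   0.0–0.1 Hz filtering, and the modified Beer–Lambert inversion
   Δc = (*L*·DPF·*E*)⁻¹·ΔOD to oxy-/deoxy-/total-hemoglobin (µM), plus
   −5…85 s block averaging.
2. **Activation GLM**: per channel, oxy-Hb is regressed on unit-peak
   boxcar⊗HRF task regressors (canonical double-gamma, peak 6 s,
   undershoot 16 s, ratio 1:6), polynomial drift and a constant;
   β̂ = (XᵀX)⁻¹Xᵀy is the activation amplitude.
3. **Group statistics**: one-sample t activation maps per group and
   condition; channel-wise one-way ANOVA across the three groups with
   Benjamini–Hochberg FDR (significant channels become the ROIs); Fisher
   LSD post hoc; paired t on ROI amplitudes between `MI` and `MI+RAS`.
   Pooled-t / ANOVA-F / Pearson-χ² utilities recompute a published
   demographics table directly from its printed summaries.
4. **Dynamic connectivity states**: sliding-window Pearson correlations of
   hemispheric region-averaged oxy-Hb residuals (task response regressed
   out), pooled over subjects and conditions, k-means clustered into
   connectivity states ordered low → high strength; K chosen by the elbow
   criterion (maximum perpendicular distance of the within-cluster
   sum-of-squares curve from its endpoint chord, computed on exemplar
   windows); per-subject state occurrence probabilities and K×K
   transition-percentage matrices (entry (x, y) = % of consecutive-window
   transitions from state x to state y, self-transitions included); group
   and condition comparisons of those dynamics.
5. **Graph metrics** per state: weighted global efficiency
   (mean 1/shortest-path with edge length 1/weight) and the Onnela
   geometric-mean weighted clustering coefficient.

Because the motivating study's raw recordings are not publicly deposited,
the package ships a first-class **synthetic-cohort generator** with known
ground truth: group-specific HRF amplitudes (freezers respond weakly
during plain imagery and are restored under auditory cueing),
physiological noise (Mayer waves, respiration, cardiac pulsation, drift,
white noise), motion artifacts (spikes and baseline steps in OD units),
and a hidden three-regime Markov process driving region-level connectivity
— so every stage is testable end to end without any download.

## Worked example

Recompute the demographics-table statistics from printed group summaries:

```bash
$ nirstates table1
              variable    test  statistic      df     p                          note
                gender    chi2      0.834       2 0.659
                   age   anova      0.684 (2, 52) 0.509
       education_years   anova      0.203 (2, 52) 0.817
disease_duration_years       t      2.092      43 0.042
               ledd_mg       t      3.337      43 0.002
             updrs_iii       t      1.806      43 0.078
              hy_stage ranksum        NaN           NaN not computable from summaries
                   fab   anova      0.600 (2, 52) 0.553
                  moca   anova      0.938 (2, 52) 0.398
```

The χ² of 0.834 for sex and the pooled t of 3.337 for levodopa-equivalent
daily dose (LEDD) match the published 0.834 and 3.336 (the tiny t
difference comes from the one-decimal rounding of the printed summaries);
the Hoehn–Yahr rank-sum statistic needs the raw ordinal stages and cannot
be reconstructed from medians/quartiles.

Run the full simulated study (21 PD+FOG / 24 PD−FOG / 10 HC subjects) in
Python:

```python
import nirstates as ns

report = ns.run_study(ns.StudyConfig(seed=0, out_dir="study_out"))
print(report.state_summary["K"])                  # 3
print(report.state_summary["centroid_strength"])  # [0.051, 0.154, 0.715]
print(report.paired[report.paired.channel == 28])
#  channel   group         t             p  mean_diff
#       28  PD+FOG -8.205483  7.860485e-08  -0.524316
#       28  PD-FOG  1.355204  1.885136e-01   0.090713
#       28      HC  2.968227  1.574769e-02   0.281475
```

The elbow criterion recovers the three generating connectivity regimes
(low/medium/high strength, mean centroid correlations 0.05 / 0.15 / 0.72
after estimation attenuation), and the paired t table reproduces the
study's qualitative finding: only the freezing group's supplementary-motor
amplitude (channel 28, at Cz) changes significantly between un-cued and
cued imagery — its response is "rescued" by the auditory rhythm.  The
per-state graph metrics are strength-ordered: global efficiency
0.06 / 0.35 / 0.72 and clustering coefficient 0.35 / 0.37 / 0.87 for the
low / medium / high states.  All intermediate tables (betas, activation
maps, ANOVA, state occurrence/transitions, dynamics tests) are written to
`study_out/` as CSV/JSON.

The same stages are scriptable from the shell: `nirstates simulate`,
`preprocess`, `glm`, `stats`, `dfc`, `report`, `table1` (see `--help`).

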