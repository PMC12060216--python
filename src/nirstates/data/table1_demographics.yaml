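# Demographic and clinical summaries of the three study groups
# (PD+FOG n=21, PD-FOG n=24, HC n=10), as printed: mean/sd for continuous
# variables, counts for categorical ones, median/IQR for ordinal stage.
# The rank-sum row cannot be recomputed from medians/quartiles and is
# marked accordingly by the table builder.
gender:
  test: chi2
  categories: [male, female]
  counts:
    PD+FOG: [12, 9]
    PD-FOG: [13, 11]
    HC: [4, 6]
age:
  test: anova
  groups:
    PD+FOG: {mean: 71.3, sd: 6.5, n: 21}
    PD-FOG: {mean: 69.4, sd: 6.4, n: 24}
    HC: {mean: 68.6, sd: 8.4, n: 10}
education_years:
  test: anova
  groups:
    PD+FOG: {mean: 10.9, sd: 2.2, n: 21}
    PD-FOG: {mean: 11.4, sd: 2.3, n: 24}
    HC: {mean: 11.1, sd: 4.0, n: 10}
disease_duration_years:
  test: t
  groups:
    PD+FOG: {mean: 7.5, sd: 3.0, n: 21}
    PD-FOG: {mean: 5.0, sd: 4.7, n: 24}
ledd_mg:
  test: t
  groups:
    PD+FOG: {mean: 734.9, sd: 210.5, n: 21}
    PD-FOG: {mean: 496.2, sd: 261.9, n: 24}
updrs_iii:
  test: t
  groups:
    PD+FOG: {mean: 33.9, sd: 11.3, n: 21}
    PD-FOG: {mean: 28.3, sd: 9.5, n: 24}
hy_stage:
  test: ranksum
  groups:
    PD+FOG: {median: 2.0, q1: 2.0, q3: 3.0, n: 21}
    PD-FOG: {median: 2.0, q1: 2.0, q3: 2.0, n: 24}
fab:
  test: anova
  groups:
    PD+FOG: {mean: 15.9, sd: 2.0, n: 21}
    PD-FOG: {mean: 16.3, sd: 2.4, n: 24}
    HC: {mean: 16.8, sd: 1.9, n: 10}
moca:
  test: anova
  groups:
    PD+FOG: {mean: 22.9, sd: 2.4, n: 21}
    PD-FOG: {mean: 23.3, sd: 2.9, n: 24}
    HC: {mean: 24.4, sd: 3.6, n: 10}
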