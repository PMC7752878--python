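# Default synthetic esophagectomy cohort (n = 1737).
#
# Covariate marginals are the published nationwide-cohort composition
# (counts normalised to probabilities).  The age distribution is a truncated
# skew-normal on [18, 89] tuned so the median is ~65.6 years and the four
# age-band frequencies (<60, 60-69, 70-74, 75+) are approximately matched.
#
# The truth model generates death times on the logit-of-instantaneous-
# probability scale: logit g = b0 + b_t*t + b_age*(age-65) + b_at*(age-65)*t
# + covariate effects.  The intercept and time slope are calibrated so the
# population-average 90-day and 5-year death probabilities are 0.112 and
# 0.748.  The age effect is OR 1.05 per year at surgery, attenuating with
# follow-up time (negative age-by-time interaction), mirroring a stronger
# short-term than long-term age association.  Non-age covariate effects are
# order-of-magnitude choices (true values unreported in the source cohort):
# they are directionally sensible (higher comorbidity, advanced stage and
# involved margins increase mortality) but not estimates.
n: 1737
seed: 20870
covariate_marginals:
  sex: {male: 0.7518711571675303, female: 0.2481288428324697}
  education: {"<=9": 0.5118019573978123, "10-12": 0.3592400690846287, ">12": 0.12895797351755903}
  cci: {"0": 0.5549798502590674, "1": 0.28267127231433506, "2+": 0.16234887742659758}
  neoadjuvant: {"no": 0.6764536557282672, "yes": 0.3235463442717329}
  histology: {adenocarcinoma: 0.4427173287276914, squamous: 0.5572826712723085}
  stage: {"0-II": 0.5998848589521014, "III-IV": 0.40011514104789866}
  margin: {"R0": 0.846286700057571, "R1-R2": 0.15371329994242947}
age_dist:
  a: -3.1855
  loc: 76.297
  scale: 15.6521
  min: 18.0
  max: 89.0
truth_spec:
  time_form: linear
  time_knots: null
  n_time_knots: 3
  age_form: linear
  age_knots: null
  n_age_knots: 3
  covariates: [sex, education, cci, neoadjuvant, histology, stage, margin]
  interactions: [[age, time]]
truth_coefs:
  "(Intercept)": -1.175739
  time: -0.203229
  age: 0.04879016416943205        # log(1.05) per year of age at t = 0
  "age:time": -0.0068             # age OR decays to ~1.015/yr by 5 years
  "sex[female]": -0.2231435513142097
  "education[10-12]": -0.05129329438755058
  "education[>12]": -0.10536051565782631
  "cci[1]": 0.26236426446749106
  "cci[2+]": 0.47000362924573563
  "neoadjuvant[yes]": 0.09531017980432493
  "histology[squamous]": 0.1823215567939546
  "stage[III-IV]": 0.7884573603642703
  "margin[R1-R2]": 0.6931471805599453
cci_age_tilt: 0.35
cancer_death_prob:
  "0-II": 0.85
  "III-IV": 0.95
admin_censor_years: 6.0
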