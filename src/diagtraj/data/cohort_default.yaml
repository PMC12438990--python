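# Default synthetic-cohort calibration.
#
# Anchored quantities (registry-style cohort structure): proportion of girls
# 0.4226; girls' leading entry diagnoses SAD 23.0%, ED 11.9%, ADHD 9.7%;
# boys' leading entry diagnoses ADHD 24.7%, ASD 19.3%, ODD 6.2%; bipolar
# disorder the smallest category in both sexes (~0.21% girls, ~0.14% boys);
# earliest mean onset ages for AD and ASD (8.1-8.9 y), latest for SUD and BD
# (15.6-16.2 y); boys diagnosed earlier than girls in every category except
# SUD, with BD and TD tied.  Stay probabilities are set so the expected
# 10-year shift prevalence is 46.7% for girls and 37.6% for boys
# (stay = (1 - p_shift)^(1/9)).  All other shares and ages are plausible
# fill-ins, not estimates of any real cohort; see docs/methods.md.
n_persons: 1000
sex_split: 0.4226
seed: 2026
entry_window: ["1996-01-01", "2011-12-31"]
p_death: 0.0005
p_emigrate: 0.002
education_mixture: {SHORT: 0.20, MEDIUM: 0.45, LONG: 0.35}
onset_age_sd: 2.2
stay_probability: {F: 0.9325, M: 0.9494}
d1_mixture:
  F:
    SUD: 2.0
    SZ: 2.2
    BD: 0.21
    SRD: 8.0
    OMD: 1.0
    AND: 7.7
    OCD: 3.0
    SAD: 23.0
    SOM: 3.5
    ED: 11.9
    PD: 1.29
    ID: 3.0
    ODD: 5.0
    ASD: 6.5
    ADHD: 9.7
    CD: 2.0
    AD: 2.5
    TD: 1.5
    OTHER: 6.0
  M:
    SUD: 2.0
    SZ: 1.5
    BD: 0.14
    SRD: 3.5
    OMD: 0.7
    AND: 6.0
    OCD: 2.8
    SAD: 10.0
    SOM: 2.0
    ED: 0.8
    PD: 0.5
    ID: 3.8
    ODD: 6.2
    ASD: 19.3
    ADHD: 24.7
    CD: 4.56
    AD: 3.0
    TD: 3.5
    OTHER: 5.0
onset_age_mean:
  F:
    SUD: 15.6
    SZ: 15.5
    BD: 16.0
    SRD: 14.8
    OMD: 15.0
    AND: 12.5
    OCD: 13.0
    SAD: 13.6
    SOM: 13.4
    ED: 14.7
    PD: 15.5
    ID: 10.2
    ODD: 9.6
    ASD: 8.9
    ADHD: 10.4
    CD: 11.6
    AD: 8.7
    TD: 10.6
    OTHER: 11.2
  M:
    SUD: 15.8
    SZ: 15.2
    BD: 16.0
    SRD: 14.4
    OMD: 14.6
    AND: 11.8
    OCD: 12.3
    SAD: 12.9
    SOM: 12.7
    ED: 13.8
    PD: 15.1
    ID: 9.6
    ODD: 9.0
    ASD: 8.4
    ADHD: 9.6
    CD: 11.0
    AD: 8.1
    TD: 10.6
    OTHER: 10.6
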