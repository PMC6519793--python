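study
studies
substudy
substudies
survey
surveys
experiment
experiments
investigation
investigations
examination
examinations
assay
assays
trial
trials
pilot-study
case-study
case-studies
field-study
cohort-study
followup
follow-up
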