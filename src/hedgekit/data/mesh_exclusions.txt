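# MeSH descriptors excluded from candidate-term frequency analysis because
# they are not semantically associated with a clinical topic: check tags for
# species, gender and age group, and study-design / housekeeping headings.
# Editable; matched case-insensitively against bare descriptors.
Humans
Animals
Male
Female
Adult
Middle Aged
Aged
Aged, 80 and over
Young Adult
Adolescent
Child
Child, Preschool
Infant
Infant, Newborn
Prospective Studies
Retrospective Studies
Cross-Sectional Studies
Cohort Studies
Follow-Up Studies
Longitudinal Studies
Case-Control Studies
Double-Blind Method
Single-Blind Method
Randomized Controlled Trials as Topic
Clinical Trials as Topic
Research Design
Time Factors
Treatment Outcome
Risk Factors
Severity of Illness Index
Questionnaires
Surveys and Questionnaires
Reproducibility of Results
Sensitivity and Specificity
Predictive Value of Tests
Data Interpretation, Statistical
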