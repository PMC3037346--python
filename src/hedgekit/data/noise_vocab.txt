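# Background vocabulary for synthetic corpora. Deliberately free of the
# tokens used by shipped fixture terms so noise text can never inflate a
# planted term's record occurrence. Fixed list, not a live dictionary, so
# generation is stable across environments.
adherence
ambulatory
anticoagulation
appointment
baseline
biomarker
capacity
caregiver
clinic
cohort
community
comorbidity
counselling
discharge
dosage
education
eligibility
enrolment
exercise
fatigue
frailty
guidance
haemoglobin
hospitalisation
inpatient
intervention
interview
kidney
lifestyle
medication
monitoring
mortality
nurse
nutrition
outcome
outpatient
pathway
pharmacist
polypharmacy
prognosis
programme
protocol
quality
readmission
recruitment
referral
registry
rehabilitation
renal
resource
screening
selfcare
survey
symptom
telehealth
titration
tolerability
training
utilisation
wellbeing
workload
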