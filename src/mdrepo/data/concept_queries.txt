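# Concept queries for the bottom-up standardization evaluation.
# Tab-separated: group <TAB> query.  Six concepts per group.
CDASH vital signs	Body height
CDASH vital signs	Body Weight
CDASH vital signs	Diastolic BP
CDASH vital signs	Systolic BP
CDASH vital signs	Pulse
CDASH vital signs	Body Temperature
Most frequent LOINC codes	Creatinine
Most frequent LOINC codes	Hemoglobin
Most frequent LOINC codes	Potassium
Most frequent LOINC codes	Glucose
Most frequent LOINC codes	Sodium
Most frequent LOINC codes	Urea nitrogen
Ischaemic heart disease concepts	Myocardial infarction
Ischaemic heart disease concepts	Coronary Artery Bypass Surgery
Ischaemic heart disease concepts	Angina Pectoris
Ischaemic heart disease concepts	Myocardial Ischemia
Ischaemic heart disease concepts	Coronary heart disease
Ischaemic heart disease concepts	Coronary revascularization
Stroke concepts	Cerebrovascular accident
Stroke concepts	Hemorrhage
Stroke concepts	Transient Ischemic Attack
Stroke concepts	Muscle Weakness
Stroke concepts	Grip strength test left hand
Stroke concepts	Dysarthria
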