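surface	preferred_term	code	category	source	domain_code
total white blood cell	Leukocyte Count	WBC	STUDY_TEST	SEND_CORE	LB
white blood cell count	Leukocyte Count	WBC	STUDY_TEST	SEND_CORE	LB
white blood cells	Leukocyte Count	WBC	STUDY_TEST	SEND_CORE	LB
leukocyte count	Leukocyte Count	WBC	STUDY_TEST	SEND_CORE	LB
absolute lymphocyte	Lymphocyte Count	LYM	STUDY_TEST	SEND_CORE	LB
lymphocyte count	Lymphocyte Count	LYM	STUDY_TEST	SEND_CORE	LB
lymphocytes	Lymphocyte Count	LYM	STUDY_TEST	SEND_CORE	LB
platelet count	Platelet Count	PLAT	STUDY_TEST	SEND_CORE	LB
platelet counts	Platelet Count	PLAT	STUDY_TEST	SEND_CORE	LB
platelets	Platelet Count	PLAT	STUDY_TEST	SEND_CORE	LB
reticulocytes	Reticulocyte Count	RETI	STUDY_TEST	SEND_CORE	LB
reticulocyte count	Reticulocyte Count	RETI	STUDY_TEST	SEND_CORE	LB
erythrocyte count	Erythrocyte Count	RBC	STUDY_TEST	SEND_CORE	LB
red blood cells	Erythrocyte Count	RBC	STUDY_TEST	SEND_CORE	LB
hemoglobin	Hemoglobin	HGB	STUDY_TEST	SEND_CORE	LB
haemoglobin	Hemoglobin	HGB	STUDY_TEST	SEND_CORE	LB
hematocrit	Hematocrit	HCT	STUDY_TEST	SEND_CORE	LB
neutrophil count	Neutrophil Count	NEUT	STUDY_TEST	SEND_CORE	LB
neutrophils	Neutrophil Count	NEUT	STUDY_TEST	SEND_CORE	LB
eosinophils	Eosinophil Count	EOS	STUDY_TEST	SEND_CORE	LB
basophils	Basophil Count	BASO	STUDY_TEST	SEND_CORE	LB
monocytes	Monocyte Count	MONO	STUDY_TEST	SEND_CORE	LB
albumin	Albumin	ALB	STUDY_TEST	SEND_CORE	LB
total protein	Protein	PROT	STUDY_TEST	SEND_CORE	LB
glucose	Glucose	GLUC	STUDY_TEST	SEND_CORE	LB
cholesterol	Cholesterol	CHOL	STUDY_TEST	SEND_CORE	LB
triglycerides	Triglycerides	TRIG	STUDY_TEST	SEND_CORE	LB
serum calcium	Calcium	CA	STUDY_TEST	SEND_CORE	LB
calcium	Calcium	CA	STUDY_TEST	SEND_CORE	LB
phosphorus	Phosphorus	PHOS	STUDY_TEST	SEND_CORE	LB
alanine aminotransferase	Alanine Aminotransferase	ALT	STUDY_TEST	SEND_CORE	LB
aspartate aminotransferase	Aspartate Aminotransferase	AST	STUDY_TEST	SEND_CORE	LB
alkaline phosphatase	Alkaline Phosphatase	ALP	STUDY_TEST	SEND_CORE	LB
total bilirubin	Bilirubin	BILI	STUDY_TEST	SEND_CORE	LB
bilirubin	Bilirubin	BILI	STUDY_TEST	SEND_CORE	LB
urea nitrogen	Urea Nitrogen	UREAN	STUDY_TEST	SEND_CORE	LB
creatinine	Creatinine	CREAT	STUDY_TEST	SEND_CORE	LB
sodium	Sodium	SODIUM	STUDY_TEST	SEND_CORE	LB
potassium	Potassium	K	STUDY_TEST	SEND_CORE	LB
prothrombin time	Prothrombin Time	PT	STUDY_TEST	SEND_CORE	LB
body weight gain	Weight Gain	BWGAIN	STUDY_TEST	SEND_CORE	BW
weight gain	Weight Gain	BWGAIN	STUDY_TEST	SEND_CORE	BW
body weight	Body Weight	BW	STUDY_TEST	SEND_CORE	BW
body weights	Body Weight	BW	STUDY_TEST	SEND_CORE	BW
food consumption	Food Consumption	FC	STUDY_TEST	SEND_CORE	FW
food intake	Food Consumption	FC	STUDY_TEST	SEND_CORE	FW
water consumption	Water Consumption	WC	STUDY_TEST	SEND_CORE	FW
liver weight	Liver Weight	LIVERWT	STUDY_TEST	SEND_CORE	OM
kidney weight	Kidney Weight	KIDNEYWT	STUDY_TEST	SEND_CORE	OM
heart rate	Heart Rate	HR	STUDY_TEST	SEND_CORE	VS
urine volume	Urine Volume	VOLUME	STUDY_TEST	SEND_CORE	UR
specific gravity	Specific Gravity	SPGRAV	STUDY_TEST	SEND_CORE	UR
necrosis	Necrosis	NECR	FINDING	SEND_CORE	MI
hepatocellular hypertrophy	Hepatocellular Hypertrophy	HEPHYP	FINDING	SEND_CORE	MI
hypertrophy	Hypertrophy	HYPT	FINDING	SEND_CORE	MI
atrophy	Atrophy	ATRO	FINDING	SEND_CORE	MI
degeneration	Degeneration	DEGN	FINDING	SEND_CORE	MI
vacuolation	Vacuolation	VACU	FINDING	SEND_CORE	MI
inflammation	Inflammation	INFL	FINDING	SEND_CORE	MI
fibrosis	Fibrosis	FIBR	FINDING	SEND_CORE	MI
mineralization	Mineralization	MINR	FINDING	SEND_CORE	MI
mineralisation	Mineralization	MINR	FINDING	SEND_CORE	MI
hyperplasia	Hyperplasia	HYPP	FINDING	SEND_CORE	MI
congestion	Congestion	CONG	FINDING	SEND_CORE	MA
hemorrhage	Hemorrhage	HEMO	FINDING	SEND_CORE	MA
haemorrhage	Hemorrhage	HEMO	FINDING	SEND_CORE	MA
enlargement	Enlargement	ENLG	FINDING	SEND_CORE	MA
vomitus	Vomitus	VOMIT	FINDING	SEND_CORE	CL
vomiting	Vomitus	VOMIT	FINDING	SEND_CORE	CL
ataxia	Ataxia	ATAX	FINDING	SEND_CORE	CL
pale	Pale	PALE	FINDING	SEND_CORE	CL
salivation	Salivation	SALIV	FINDING	SEND_CORE	CL
tremor	Tremor	TREM	FINDING	SEND_CORE	CL
tremors	Tremor	TREM	FINDING	SEND_CORE	CL
convulsions	Convulsion	CONV	FINDING	SEND_CORE	CL
lethargy	Lethargy	LETH	FINDING	SEND_CORE	CL
piloerection	Piloerection	PILO	FINDING	SEND_CORE	CL
diarrhea	Diarrhea	DIAR	FINDING	SEND_CORE	CL
diarrhoea	Diarrhea	DIAR	FINDING	SEND_CORE	CL
alopecia	Alopecia	ALOP	FINDING	SEND_CORE	CL
hypoactivity	Hypoactivity	HYPO	FINDING	SEND_CORE	CL
faeces	Faeces	FAECES	SPECIMEN	SEND_CORE	UNASSIGNED
feces	Faeces	FAECES	SPECIMEN	SEND_CORE	UNASSIGNED
kidney	Kidney	KIDNEY	SPECIMEN	SEND_CORE	UNASSIGNED
kidneys	Kidney	KIDNEY	SPECIMEN	SEND_CORE	UNASSIGNED
liver	Liver	LIVER	SPECIMEN	SEND_CORE	UNASSIGNED
heart	Heart	HEART	SPECIMEN	SEND_CORE	UNASSIGNED
lung	Lung	LUNG	SPECIMEN	SEND_CORE	UNASSIGNED
lungs	Lung	LUNG	SPECIMEN	SEND_CORE	UNASSIGNED
spleen	Spleen	SPLEEN	SPECIMEN	SEND_CORE	UNASSIGNED
stomach	Stomach	STOMACH	SPECIMEN	SEND_CORE	UNASSIGNED
thymus	Thymus	THYMUS	SPECIMEN	SEND_CORE	UNASSIGNED
urine	Urine	URINE	SPECIMEN	SEND_CORE	UNASSIGNED
salivary gland	Salivary Gland	SALGL	SPECIMEN	SEND_CORE	UNASSIGNED
salivary glands	Salivary Gland	SALGL	SPECIMEN	SEND_CORE	UNASSIGNED
adrenal gland	Adrenal Gland	ADRGL	SPECIMEN	SEND_CORE	UNASSIGNED
adrenal glands	Adrenal Gland	ADRGL	SPECIMEN	SEND_CORE	UNASSIGNED
brain	Brain	BRAIN	SPECIMEN	SEND_CORE	UNASSIGNED
bone marrow	Bone Marrow	BONMAR	SPECIMEN	SEND_CORE	UNASSIGNED
testes	Testis	TESTIS	SPECIMEN	SEND_CORE	UNASSIGNED
ovary	Ovary	OVARY	SPECIMEN	SEND_CORE	UNASSIGNED
ovaries	Ovary	OVARY	SPECIMEN	SEND_CORE	UNASSIGNED
thyroid	Thyroid	THYROID	SPECIMEN	SEND_CORE	UNASSIGNED
pancreas	Pancreas	PANCREAS	SPECIMEN	SEND_CORE	UNASSIGNED
skin	Skin	SKIN	SPECIMEN	SEND_CORE	UNASSIGNED
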