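surface	preferred_term	code	category	source	domain_code
wbc	Leukocyte Count	WBC	STUDY_TEST	SEND_EXTENSION	LB
alt	Alanine Aminotransferase	ALT	STUDY_TEST	SEND_EXTENSION	LB
ast	Aspartate Aminotransferase	AST	STUDY_TEST	SEND_EXTENSION	LB
alp	Alkaline Phosphatase	ALP	STUDY_TEST	SEND_EXTENSION	LB
bun	Urea Nitrogen	UREAN	STUDY_TEST	SEND_EXTENSION	LB
rbc	Erythrocyte Count	RBC	STUDY_TEST	SEND_EXTENSION	LB
histopathologic lesions	lesions	ETX001	FINDING	ETOX	MI
histopathological lesions	lesions	ETX001	FINDING	ETOX	MI
lesions	lesions	ETX001	FINDING	ETOX	MI
increased m:e ratio	increased M:E ratio	ETX002	FINDING	ETOX	MI
m:e ratio	M:E ratio	ETX003	FINDING	ETOX	LB
soft faeces	soft faeces	ETX004	FINDING	ETOX	CL
hunched posture	hunched posture	ETX005	FINDING	ETOX	CL
erosion	Erosion	UML001	FINDING	UMLS_LIKE	MI
erosions	Erosion	UML001	FINDING	UMLS_LIKE	MI
ulceration	Ulceration	UML002	FINDING	UMLS_LIKE	MI
edema	Edema	UML003	FINDING	UMLS_LIKE	MI
oedema	Edema	UML003	FINDING	UMLS_LIKE	MI
discoloration	Discoloration	UML004	FINDING	UMLS_LIKE	MA
mesenteric lymph node	Mesenteric Lymph Node	UML005	SPECIMEN	UMLS_LIKE	UNASSIGNED
lymph nodes	Lymph Node	UML006	SPECIMEN	UMLS_LIKE	UNASSIGNED
gall bladder	Gall Bladder	UML007	SPECIMEN	UMLS_LIKE	UNASSIGNED
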