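concept_id	preferred_label	icd10_code	malignancy_code	organ_code
F_NODULE	nodule		possible
F_GGN	ground-glass nodule		possible	lung
F_LUNG_NODULE	lung nodule		possible	lung
F_MASS	mass		possible
F_HYPO	hypoattenuating lesion		possible
F_CYST	cyst		benign
F_CANCER	cancer		malignant
F_LUNG_CANCER	lung cancer	C34	malignant	lung
F_METASTASIS	metastasis	C79	malignant
F_MALIG	malignancy		malignant
F_TUMOR	tumor		indeterminate
F_OVARIAN_TUMOR	ovarian tumor	D39	indeterminate	ovary
F_FIBROID	uterine fibroid	D25	benign	uterus
F_POSTINFLAM	post-inflammatory change		benign
F_CRYPTO	pulmonary cryptococcosis	B45	possible	lung
F_IP	interstitial pneumonia	J84		lung
F_NTM	nontuberculous mycobacterial disease	A31		lung
F_PNEUMONIA	pneumonia	J18	possible	lung
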