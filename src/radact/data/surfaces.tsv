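surface	entity_kind	concept_id	finding_kind
結節	finding	F_NODULE	observation
小結節	finding	F_NODULE	observation
多発結節	finding	F_NODULE	observation
nodule	finding	F_NODULE	observation
すりガラス結節	finding	F_GGN	observation
肺結節	finding	F_LUNG_NODULE	observation
腫瘤	finding	F_MASS	observation
低吸収域	finding	F_HYPO	observation
hypoattenuating lesion	finding	F_HYPO	observation
嚢胞	finding	F_CYST	observation
癌	finding	F_CANCER	clinical_finding
肺癌	finding	F_LUNG_CANCER	clinical_finding
lung cancer	finding	F_LUNG_CANCER	clinical_finding
転移	finding	F_METASTASIS	clinical_finding
悪性	finding	F_MALIG	clinical_finding
腫瘍	finding	F_TUMOR	clinical_finding
卵巣腫瘍	finding	F_OVARIAN_TUMOR	clinical_finding
ovarian tumor	finding	F_OVARIAN_TUMOR	clinical_finding
子宮筋腫	finding	F_FIBROID	clinical_finding
炎症後変化	finding	F_POSTINFLAM	clinical_finding
肺クリプトコッカス症	finding	F_CRYPTO	clinical_finding
間質性肺炎	finding	F_IP	clinical_finding
非結核性抗酸菌症	finding	F_NTM	clinical_finding
肺炎	finding	F_PNEUMONIA	clinical_finding
右上葉	anatomical_location	L_RUL
right upper lobe	anatomical_location	L_RUL
左肺下葉	anatomical_location	L_LLL
両肺	anatomical_location	L_BILAT_LUNG
肺	anatomical_location	L_LUNG
甲状腺	anatomical_location	L_THYROID
甲状腺右葉	anatomical_location	L_THYROID_R
子宮	anatomical_location	L_UTERUS
卵巣	anatomical_location	L_OVARY
肝臓	anatomical_location	L_LIVER
膵臓	anatomical_location	L_PANCREAS
乳房	anatomical_location	L_BREAST
腎臓	anatomical_location	L_KIDNEY
胃	anatomical_location	L_STOMACH
リンパ節	anatomical_location	L_LYMPH_NODE
増大	change	C_INCREASING
増加	change	C_INCREASING
increased	change	C_INCREASING
悪化	change	C_WORSENING
新規	change	C_NEW
出現	change	C_NEW
不変	change	C_UNCHANGED
縮小	change	C_DECREASING
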