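concept_id	preferred_label	organ_code	body_part_code
L_RUL	right upper lobe	lung	chest
L_LLL	left lower lobe	lung	chest
L_BILAT_LUNG	both lungs	lung	chest
L_LUNG	lung	lung	chest
L_THYROID	thyroid	thyroid	neck
L_THYROID_R	thyroid right lobe	thyroid	neck
L_UTERUS	uterus	uterus	pelvis
L_OVARY	ovary	ovary	pelvis
L_LIVER	liver	liver	abdomen
L_PANCREAS	pancreas	pancreas	abdomen
L_BREAST	breast	breast	chest
L_KIDNEY	kidney	kidney	abdomen
L_STOMACH	stomach	stomach	abdomen
L_LYMPH_NODE	lymph node	lymph_node	trunk
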