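concept_id	preferred_label	status_code
C_INCREASING	increasing	increasing
C_WORSENING	worsening	increasing
C_NEW	newly appeared	new
C_UNCHANGED	unchanged	unchanged
C_DECREASING	decreasing	decreasing
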