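tissue	histology	cell_line
soft_tissue	Rhabdomyosarcoma	A-204
soft_tissue	Rhabdomyosarcoma	Hs 729
soft_tissue	Rhabdomyosarcoma	KYM-1
soft_tissue	Rhabdomyosarcoma	RD
soft_tissue	Rhabdomyosarcoma	RH-30
soft_tissue	Rhabdomyosarcoma	RH-41
soft_tissue	Rhabdomyosarcoma	SJRH30
soft_tissue	Rhabdomyosarcoma	TE 441.T
soft_tissue	Rhabdomyosarcoma	TE 617.T
bone	Ewings_sarcoma	A-673
bone	Ewings_sarcoma	CADO-ES1
bone	Ewings_sarcoma	Hs 822.T
bone	Ewings_sarcoma	Hs 863.T
bone	Ewings_sarcoma	MHH-ES-1
bone	Ewings_sarcoma	RD-ES
bone	Ewings_sarcoma	SK-ES-1
bone	Ewings_sarcoma	SK-N-MC
bone	Ewings_sarcoma	TC-71
bone	Osteosarcoma	143B
bone	Osteosarcoma	G-292
bone	Osteosarcoma	HOS
bone	Osteosarcoma	Hs 870.T
bone	Osteosarcoma	Hs 888.T
bone	Osteosarcoma	MG-63
bone	Osteosarcoma	SJSA-1
bone	Osteosarcoma	T1-73
bone	Osteosarcoma	U-2 OS
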