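seed_match	gene	accession	start	end
CACTGG	VEGFA	NM_003376	483	489
CACTGG	TGFBR1	NM_004612	3355	3361
CACTGG	BCL2	NM_000633	4526	4532
ACACTGG	ETS1	NM_001143820	2708	2715
ACACTGG	JUNB	NM_002229	119	126
ACACTGG	BCL2	NM_000633	4667	4673
ACACTGG	PAX8	NM_013952	2169	2175
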