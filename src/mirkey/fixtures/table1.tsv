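grade	direction	mirna	common
GI	up	hsa-miR-452	true
GI	up	hsa-miR-487a	true
GI	up	hsa-miR-491-3p	true
GI	up	hsa-miR-200c	true
GI	up	hsa-miR-155	false
GI	up	hsa-miR-340	false
GI	up	hsa-miR-365	false
GI	up	hsa-miR-493	false
GI	up	hsa-miR-519e	false
GI	up	hsa-miR-520a-5p	false
GI	up	hsa-miR-768-3p	false
GI	up	hsa-miR-297	false
GI	down	hsa-miR-125b	true
GI	down	hsa-miR-142-3p	true
GI	down	hsa-miR-199a-5p	true
GI	down	hsa-miR-22	true
GI	down	hsa-miR-299-3p	true
GI	down	hsa-miR-29a	true
GI	down	hsa-miR-429	true
GI	down	hsa-miR-532-5p	true
GI	down	hsa-miR-148a	false
GI	down	hsa-miR-632	false
GI	down	hsa-miR-637	false
GI	down	miRplus-17952	false
GII	up	hsa-miR-452	true
GII	up	hsa-miR-487a	true
GII	up	hsa-miR-491-3p	true
GII	up	hsa-miR-200c	true
GII	up	hsa-miR-297	false
GII	up	hsa-miR-299-5p	false
GII	up	hsa-miR-29b-1	false
GII	up	hsa-miR-32	false
GII	up	hsa-miR-369-3p	false
GII	up	hsa-miR-423-5p	false
GII	up	hsa-miR-486-5p	false
GII	up	hsa-miR-519d	false
GII	up	hsa-miR-574-5p	false
GII	up	hsa-miR-662	false
GII	up	hsa-miR-766	false
GII	up	hsa-miR-768-3p	false
GII	up	hsa-miR-92b	false
GII	up	miRplus-17858	false
GII	down	hsa-miR-125b	true
GII	down	hsa-miR-142-3p	true
GII	down	hsa-miR-199a-5p	true
GII	down	hsa-miR-22	true
GII	down	hsa-miR-299-3p	true
GII	down	hsa-miR-29a	true
GII	down	hsa-miR-429	true
GII	down	hsa-miR-532-5p	true
GII	down	hsa-miR-147b	false
GII	down	hsa-miR-23b	false
GII	down	hsa-miR-26a	false
GII	down	hsa-miR-29b	false
GII	down	hsa-miR-571	false
GII	down	hsa-miR-637	false
GII	down	hsa-miR-99a	false
GII	down	hsa-miR-99b	false
GII	down	miRplus-17952	false
GIII	up	hsa-miR-452	true
GIII	up	hsa-miR-487a	true
GIII	up	hsa-miR-491-3p	true
GIII	up	hsa-miR-200c	true
GIII	up	hsa-miR-125a-5p	false
GIII	up	hsa-miR-183	false
GIII	up	hsa-miR-184	false
GIII	up	hsa-miR-208	false
GIII	up	hsa-miR-214	false
GIII	up	hsa-miR-381	false
GIII	up	hsa-miR-520a-5p	false
GIII	up	hsa-miR-526b	false
GIII	up	hsa-miR-551a	false
GIII	up	hsa-miR-583	false
GIII	up	hsa-miR-766	false
GIII	up	hsa-miR-768-3p	false
GIII	up	hsa-miR-890	false
GIII	up	hsa-miR-891a	false
GIII	up	miRplus-17955	false
GIII	down	hsa-miR-125b	true
GIII	down	hsa-miR-142-3p	true
GIII	down	hsa-miR-199a-5p	true
GIII	down	hsa-miR-22	true
GIII	down	hsa-miR-299-3p	true
GIII	down	hsa-miR-29a	true
GIII	down	hsa-miR-429	true
GIII	down	hsa-miR-532-5p	true
GIII	down	hsa-miR-143	false
GIII	down	hsa-miR-23b	false
GIII	down	hsa-miR-26a	false
GIII	down	hsa-miR-30b	false
GIII	down	hsa-miR-622	false
GIII	down	hsa-miR-765	false
GIII	down	hsa-let-7g	false
GIII	down	hsa-let-7i	false
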