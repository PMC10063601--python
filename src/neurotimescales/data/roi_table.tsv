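name	description	source	x	y	z	radius_mm
W_rPCG	right Post-Central Gyrus	W	58	-14	44	6
W_lPCG	left Post-Central Gyrus	W	-58	-14	40	6
W_rMTG	right Middle Temporal Gyrus	W	60	22	6	6
W_lMTG	left Middle Temporal Gyrus	W	-70	-26	6	6
W_rIOG	right Inferior Occipital Gyrus	W	52	-74	6	6
W_rIPL	right Inferior Parietal Lobule	W	50	-44	32	6
W_rMidIns	right Middle Insula	W	50	10	4	6
W_rCaud	right Caudate	W	14	20	12	6
U_rOccFusG	right Occipital Fusiform Gyrus	U	27	-88	14	6
U_lSupOccG	left Superior Occipital Gyrus	U	-15	-91	19	6
U_rSupOccG	right Superior Occipital Gyrus	U	18	-79	25	6
U_lLatOccC	left Lateral Occipital Cortex	U	-42	-70	1	6
U_rPostCenG	right Post-Central Gyrus	U	42	-31	64	6
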