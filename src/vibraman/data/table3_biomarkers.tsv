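mode_index	wavenumber	drug	description
72	767	clopidogrel	Rocking H-C2-H, H-C3-H, H-C2-H, H-C4-H (arginine) and scissoring C7-C8-C9, vibration of hydrogen atoms out of the plane of the aromatic ring (metabolite)
85	905	clopidogrel	Twisting H-C2-H, H-C3-H, H-C4-H, stretching C5-N3, C5-N4 (arginine) and wagging H-O3-C9 (metabolite)
93	997	clopidogrel	Stretching of 1-azacyclohexnene-3 and scissoring H-S-C6 (metabolite) and wagging N1-H (arginine)
96	1017	clopidogrel	Stretching C2-C3-C4 (arginine) and stretching C1-O1-C2 (metabolite)
97	1019	clopidogrel	Stretching C2-C3-C4 (arginine) and stretching C1-O1-C2 (metabolite)
146	1450	clopidogrel	Scissoring H-O2-C6 (arginine) and scissoring H-C9-H (metabolite)
147	1451	clopidogrel	Scissoring H-O2-C6 (arginine) and scissoring H-C9-H (metabolite)
151	1474	clopidogrel	Scissoring H-C2-H, H-C3-H (arginine) and scissoring H-C1-H (metabolite)
152	1475	clopidogrel	Vibration of hydrogen atoms in the plane of the aromatic ring (metabolite) and scissoring H-C2-H, H-C3-H (arginine)
153	1475	clopidogrel	Scissoring H-C1-H (metabolite) and scissoring H-C2-H, H-C3-H (arginine)
163	1731	clopidogrel	Stretching C2=O2 (metabolite) and scissoring H-N1-H (arginine)
164	1733	clopidogrel	Stretching C2=O2, scissoring C9-O3-H (metabolite) and stretching C6=O1 (arginine)
165	1764	clopidogrel	Stretching C2=O2 (metabolite) and stretching C6=O1, scissoring C9-O3-H (arginine)
32	450	aspirin	Twisting H-N1-H, scissoring C1-C2-C3 (arginine) and scissoring C9-O4-H (aspirin)
33	465	aspirin	Rocking H-N1-H (arginine) and rocking H-O4-C9 (aspirin)
35	492	aspirin	Rocking H-N1-H (arginine) and rocking H-O4-C9 (aspirin)
37	510	aspirin	Wagging H-N4-H
38	516	aspirin	Wagging H-N4-H (arginine) and deformation of the aromatic ring in the ring plane (aspirin)
40	541	aspirin	Deformation of the aromatic ring in the ring plane, scissoring O4-C9=O3 (aspirin) and rocking H-C3-H (arginine)
41	544	aspirin	Scissoring O3=C9-C4 and aromatic ring stretching
45	608	aspirin	Deformation of the aromatic ring in the ring plane, scissoring O4-C9=O3
49	680	aspirin	Aromatic ring stretching (aspirin) and rocking H-N3-H (arginine)
56	797	aspirin	Wagging H-N3-H (arginine) and change in hydrogen bond length
58	814	aspirin	Aromatic ring stretching (aspirin) and wagging H-N3-H (arginine)
72	1060	aspirin	Rocking H-N3-H and change in hydrogen bond length
75	1087	aspirin	Rocking H-N4-H, H-N3-H (arginine) and vibration of hydrogen atoms in the plane of the ring
91	1338	aspirin	Twisting H-C2-H (arginine) and aromatic ring deformation (aspirin)
92	1339	aspirin	Twisting H-C2-H (arginine) and aromatic ring deformation (aspirin)
108	1579	aspirin	Scissoring H-N3-H and C5-N2-H, change in hydrogen bond length
109	1621	aspirin	Scissoring H-N3-H, stretching N2-C5-N3, change in hydrogen bond length
114	1708	aspirin	Scissoring H-N3-H, stretching N3-C5 (arginine) and stretching O2=C2 (aspirin)
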