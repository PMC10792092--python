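index	wavenumber	raman_activity	fragment	description
30	391	0.54	ligand	Deformation of the aromatic ring out of the plane of the ring
31	422	0.59	ligand	Scissoring O3=C9-C4 and aromatic ring stretching
32	450	0.01	joint	Twisting H-N1-H, scissoring C1-C2-C3 (arginine) and scissoring C9-O4-H (aspirin)
33	465	0.22	joint	Rocking H-N1-H (arginine) and rocking H-O4-C9 (aspirin)
34	485	0.10	residue	Wagging H-N4-H
35	492	0.11	joint	Rocking H-N1-H (arginine) and rocking H-O4-C9 (aspirin)
36	506	0.21	ligand	Twisting H-O4-C9 and deformation of the aromatic ring out of the plane of the ring
37	510	0.16	residue	Wagging H-N4-H
38	516	0.10	joint	Wagging H-N4-H (arginine) and deformation of the aromatic ring in the ring plane (aspirin)
39	527	0.06	residue	Scissoring N4=C5-N2 and rocking H-C3-H
40	541	0.16	joint	Deformation of the aromatic ring in the ring plane, scissoring O4-C9=O3 (aspirin) and rocking H-C3-H (arginine)
41	544	0.10	joint	Scissoring O3=C9-C4 and aromatic ring stretching
42	569	0.17	ligand	Wagging O1=C2-O2
43	584	0.16	joint	Scissoring N-C-N and N-C-C (arginine) and aromatic ring deformation and scissoring N2-C5-N3 (arginine)
44	592	0.18	ligand	Out-of-plane deformation of the aromatic ring
45	608	0.08	ligand	Deformation of the aromatic ring in the ring plane, scissoring O4-C9=O3
46	615	0.04	residue	Scissoring N3-C5-N2
47	643	0.11	ligand	Vibration of hydrogen atoms out of the plane of the ring
48	653	0.15	ligand	Aromatic ring stretching, scissoring O1-C2=O2 and wagging O4-C9=O3
49	680	0.27	joint	Aromatic ring stretching (aspirin) and rocking H-N3-H (arginine)
50	709	0.04	residue	Wagging N3-C5=N4 and twisting H-N3-H
51	718	0.03	residue	Rocking H-C2-H and O2=C6-O1
52	721	0.26	ligand	Aromatic ring stretching and stretching O4-C9-C4
53	731	0.09	residue	Twisting H-N3-H
54	741	0.02	residue	Rocking H-C2-H, H-C3-H, H-C4-H
55	771	0.22	ligand	Vibration of hydrogen atoms out of the plane of the ring
56	797	0.07	joint	Wagging H-N3-H (arginine) and change in hydrogen bond length
57	803	0.14	residue	Rocking H-C2-H, H-C3-H, H-C4-H and wagging H-N3-H
58	814	0.07	joint	Aromatic ring stretching (aspirin) and wagging H-N3-H (arginine)
59	862	0.08	ligand	Wagging H-C8-C7
60	865	0.02	residue	Twisting H-C2-H, H-C3-H, H-C4-H
61	907	0.05	residue	Scissoring H-N1-H
62	916	0.05	ligand	Vibration of hydrogen atoms out of the plane of the ring
63	924	0.18	ligand	Scissoring O1-C2, C2=O2 and C2-C3
64	931	0.14	residue	Twisting H-C4-H and stretching N2-C5-N3 and N2-C5=N4
65	942	0.03	residue	Wagging H-N1-H and stretching N1-C1
66	986	0.32	ligand	Aromatic ring stretching
67	1009	0.11	ligand	Deformation of the aromatic ring in the ring plane and stretching C9-O4
68	1014	0.02	ligand	Wagging H-C3-H
69	1016	0.09	residue	Stretching C2-C3-C4 and wagging H-N1-H
70	1031	0.06	residue	Stretching C2-C3-C4
71	1042	0.01	ligand	Wagging H-C3-H
72	1060	0.05	joint	Rocking H-N3-H and change in hydrogen bond length
73	1064	0.11	residue	Rocking H-N3-H
74	1084	0.01	residue	Stretching C1-C2 and rocking H-N3-H
75	1087	0.07	joint	Rocking H-N4-H, H-N3-H (arginine) and vibration of hydrogen atoms in the plane of the ring
76	1090	0.12	residue	Rocking H-N4-H, H-N3-H
77	1129	0.16	ligand	Vibration of hydrogen atoms in the plane of the ring
78	1134	0.04	residue	Stretching N1-C1-C2 and rocking H-C3-H, H-C2-H
79	1144	0.07	residue	Rocking H-N3-H, H-N4-H and stretching C4-N2-C5
80	1159	0.14	ligand	Vibration of hydrogen atoms in the plane of the ring
81	1185	0.13	residue	Twisting H-C4-H and H-N1-H
82	1191	0.29	ligand	Scissoring H-O4-C9
83	1199	0.08	residue	Twisting H-C2-H, H-C3-H, H-C4-H
84	1213	0.13	residue	Scissoring H-C1-C5 and twisting H-N1-H
85	1237	0.43	ligand	Vibration of hydrogen atoms in the plane of the ring
86	1258	0.01	residue	Wagging H-C2-H, H-C3-H
87	1270	0.40	ligand	Stretching C3-C2-O1
88	1290	0.05	residue	Wagging H-C2-H, H-C4-H and twisting H-C3-H
89	1304	0.20	ligand	Stretching O3=C9-O4, aromatic ring deformation, scissoring C9-O3-H
90	1319	0.13	residue	Twisting H-C3-H
91	1338	0.03	joint	Twisting H-C2-H (arginine) and aromatic ring deformation (aspirin)
92	1339	0.28	joint	Twisting H-C2-H (arginine) and aromatic ring deformation (aspirin)
93	1353	0.01	residue	Wagging H-C2-H, H-C4-H
94	1374	0.23	residue	Scissoring H-C3-H
95	1381	0.02	residue	Wagging H-C2-H, H-C3-H, H-C4-H
96	1399	0.06	residue	Scissoring H-N1-C1 and twisting H-N1-H
97	1403	0.02	residue	Scissoring H-N2-C5 and twisting H-N1-H
98	1409	0.20	ligand	Deformation of the aromatic ring in the ring plane
99	1429	0.24	residue	Scissoring H-N1-C1
100	1434	1.52	ligand	Vibration of hydrogen atoms in the plane of the ring
101	1453	0.22	ligand	Scissoring H-C3-H
102	1460	0.22	ligand	Scissoring H-C3-H
103	1468	0.10	residue	Scissoring H-C2-H
104	1479	0.09	residue	Scissoring H-C3-H, H-C4-H
105	1483	0.05	ligand	Vibration of hydrogen atoms in the plane of the ring
106	1496	0.03	residue	Scissoring H-C3-H, H-C4-H
107	1572	0.42	ligand	Vibration of hydrogen atoms in the plane of the ring and scissoring C9-O4-H
108	1579	0.08	joint	Scissoring H-N3-H and C5-N2-H, change in hydrogen bond length
109	1621	0.19	joint	Scissoring H-N3-H, stretching N2-C5-N3, change in hydrogen bond length
110	1647	0.61	joint	Scissoring H-N1-H (arginine) and stretching O3=C9-C4 (aspirin)
111	1657	0.57	residue	Scissoring H-N3-H, H-N4-H
112	1669	0.35	residue	Scissoring H-N1-H
113	1677	0.23	residue	Scissoring H-N3-H, stretching N3-C5
114	1708	0.28	joint	Scissoring H-N3-H, stretching N3-C5 (arginine) and stretching O2=C2 (aspirin)
115	1792	0.09	residue	Stretching C6-O1 and twisting H-N1-C1
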