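specimen_id	species	genus	id_status	site	region	depth	NCR1	ND6	ND2	COI+	MutS
unnumbered-1	Narella alaskensis	Narella	unidentified	Murray	GOA	2254?	3	3	3	3	3
1075468	Narella alaskensis	Narella	identified	Denson	GOA	2377	3	3	3	3	3
unnumbered-2	Narella alaskensis	Narella	unidentified	Murray	GOA	2511	3	3	3	3	3
1075471	Narella alaskensis	Narella	identified	Welker	GOA	2634	3	3	3	3	3
1080453	Narella alaskensis	Narella	identified	Murray	GOA	2680?	3	3	3	3	3
1075469	Narella alaskensis	Narella	identified	Dickins	GOA	2736	3	3	3	3	3
unnumbered-3	Narella alaskensis	Narella	unidentified	Murray	GOA	2264–2680′	3	3	3	3	3
Acc2042645	Narella alaskensis	Narella	unidentified	San Marcos	California	2050	3	3	3	3	3
1080454	Narella alaskensis	Narella	identified	Chirikoff	GOA	3075	3	3	20	3	3
1072109	Narella hawaiiensis	Narella	identified	Pioneer	NWHI	1743.7	9	26	3	3	9
1071215	Narella hawaiiensis	Narella	identified	Keahole	MHI	400–1492′	3	26	15	15	15
1072111-or-1072112-a	Narella dichotoma	Narella	identified	Pioneer	NWHI	1209.0	12	12	12	3	12
1072111-or-1072112-b	Narella dichotoma	Narella	identified	Pioneer	NWHI	1209.0	12	12	12	3	12
1071422	Narella dichotoma	Narella	identified	Keahole	MHI	743.21	12	19	12	3	19
1071418	Narella alata	Narella	identified	Keahole	MHI	679.44	1	1	1	1	1
1071421	Narella alata	Narella	identified	Keahole	MHI	749.56	1	1	1	1	1
1071420-a	Narella alata	Narella	identified	Keahole	MHI	749.56	1	1	1	1	1
1071420-b	Narella alata	Narella	identified	Keahole	MHI	749.56	1	1	1	1	1
1071419	Narella alata	Narella	identified	Keahole	MHI	749.56	1	1	1	1	1
1072131	Narella sp. 1	Narella	identified	E of Necker	NWHI	1812.6	1	1	8	8	8
1080450	Narella abyssalis	Narella	identified	Derickson	Aleutians	4594	2	2	2	27	2
1080447	Narella bayeri	Narella	identified	Derickson	Aleutians	3292	2	2	2	2	2
1080448	Narella bayeri	Narella	identified	Aleutian Slope	Aleutians	3277	21	2	2	2	2
1080446	Narella bayeri	Narella	identified	Derickson	Aleutians	4091	21	2	2	2	2
1080449	Narella cristata	Narella	identified	Derickson	Aleutians	3385	21	2	2	21	2
1072118	Narella macrocalyx	Narella	identified	SE of Laysan	NWHI	1206.0	11	5	5	11	11
1072133	Narella macrocalyx	Narella	identified	E of Necker	NWHI	1443.4	11	5	5	11	11
1072122	Narella macrocalyx	Narella	identified	E of Necker	NWHI	1697.4	11	5	5	11	11
1072105	Narella macrocalyx	Narella	identified	Pioneer	NWHI	1706.0	11	5	5	11	11
1072116	Narella sp. 2	Narella	identified	SE of Laysan	NWHI	1807.0	5	5	4	5	4
1072108	Narella sp. cf. macrocalyx	Narella	identified	Pioneer	NWHI	1743.7	5	5	5	5	4
1072103	Narella sp. cf. macrocalyx	Narella	identified	Pioneer	NWHI	1802.0	5	5	5	5	4
1072117	Narella sp. cf. macrocalyx	Narella	identified	SE of Laysan	NWHI	1807.0	5	5	5	5	4
1080452	Narella arbuscula	Narella	identified	Derickson	Aleutians	3465	5	5	5	5	4
1080451	Narella arbuscula	Narella	identified	Derickson	Aleutians	2775	5	5	5	4	4
1075465	Narella arbuscula	Narella	identified	Giacomini	GOA	2818.6	5	5	5	5	5
unnumbered-4	Narella sp.	Narella	unidentified	Giacomini	GOA	2818.6	5	5	5	5	5
1075466	Narella arbuscula	Narella	identified	Giacomini	GOA	2818.8	5	5	5	5	5
1075467	Narella arbuscula	Narella	identified	Giacomini	GOA	2810–2818′	5	5	5	5	5
1154063	Callogorgia gilberti	Callogorgia	identified	Makapuu	MHI	411.3	10	10	10	10	10
1075379	Parastenella ramosa	Parastenella	identified	Pratt	GOA	918	1	17	17	17	17
1082620-or-1082624	Parastenella gymnogaster	Parastenella	identified	Marchand	GOA	2417	1	17	2	17	23
unnumbered-5	Parastenella sp.	Parastenella	unidentified	Welker	GOA	1084	1	22	2	17	22
1082639	Parastenella ramosa	Parastenella	identified	Warwick	GOA	808–872′	1	22	2	17	22
1075478	Primnoa pacifica willeyi	Primnoa	identified	Dickins	GOA	755	1	7	7	7	7
1082615	Calyptrophora laevispinosa	Calyptrophora	identified	Patton	GOA	1834/1778′	6	6	6	6	6
1082617	Calyptrophora laevispinosa	Calyptrophora	identified	Patton	GOA	1993	6	6	6	6	6
1075472	Calyptrophora laevispinosa	Calyptrophora	identified	Welker	GOA	2757	6	6	6	25	6
1082616	Calyptrophora laevispinosa	Calyptrophora	identified	Patton	GOA	1778–3075′	6	6	6	25	6
1071947	Calyptrophora wyvillei	Calyptrophora	identified	Pioneer	NWHI	1200	18	18	6	18	18
1071423	Calyptrophora wyvillei	Calyptrophora	identified	Keahole	MHI	935	18	18	6	18	18
1072130	Calyptrophora wyvillei	Calyptrophora	identified	E of Necker	NWHI	1278	13	13	13	13	13
1072135	Paracalyptrophora hawaiiensis	Paracalyptrophora	identified	Twin Banks	NWHI	407	14	14	14	14	14
1071245	Paracalyptrophora hawaiiensis	Paracalyptrophora	identified	Cross	MHI	388.71	14	14	14	14	14
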