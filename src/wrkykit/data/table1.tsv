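# Transcribed family-survey table: 63 WRKY proteins with conserved motif,
# zinc-finger signature, domain count and group assignment.
# columns: gene_name, annotation_id, orf_aa, motifs (slash-joined),
#          signatures (slash-joined), terminals (slash-joined), motif_count, group
gene_name	annotation_id	orf_aa	motifs	signatures	terminals	motif_count	group
DoWRKY1	Dendrobium_GLEAN_10130608	529	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X5-C-X23-HXH	N/C	2	I
DoWRKY7	Dendrobium_GLEAN_10115484	638	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY9	Dendrobium_GLEAN_10112830	434	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY12	Dendrobium_GLEAN_10109483	542	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY15	Dendrobium_GLEAN_10100432	549	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY20	Dendrobium_GLEAN_10094986	717	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY25	Dendrobium_GLEAN_10089661	611	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY32	Dendrobium_GLEAN_10077269	578	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY37	Dendrobium_GLEAN_10074853	731	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY39	Dendrobium_GLEAN_10074607	557	WRKYGQK/WRKYGQK	C-X4-C-X22-HXH/C-X4-C-X23-HXH	N/C	2	I
DoWRKY62	Dendrobium_GLEAN_10044500	302	WRKYGQK	C-X4-C-X23-HXH	only	1	I
DoWRKY63	Dendrobium_GLEAN_10044501	353	WRKYGQK	C-X4-C-X22-HXH	only	1	I
DoWRKY80	Dendrobium_GLEAN_10003356	330	WRKYGQK	C-X4-C-X22-HXH	only	1	I
DoWRKY81	Dendrobium_GLEAN_10000561	135	WRKYGQK	C-X4-C-X22-HXH	only	1	I
DoWRKY2	Dendrobium_GLEAN_10129229	277	WRKYGQK	C-X5-C-X22-HXH	only	1	IIa
DoWRKY43	Dendrobium_GLEAN_10069437	309	WRKYGQK	C-X5-C-X23-HXH	only	1	IIa
DoWRKY73	Dendrobium_GLEAN_10020166	302	WRKYGQK	C-X5-C-X23-HXH	only	1	IIa
DoWRKY77	Dendrobium_GLEAN_10013350	225	WRKYGQK	C-X5-C-X23-HXH	only	1	IIa
DoWRKY42	Dendrobium_GLEAN_10070674	451	WRKYGQK	C-X5-C-X23-HXH	only	1	IIb
DoWRKY53	Dendrobium_GLEAN_10059328	570	WRKYGQK	C-X5-C-X23-HXH	only	1	IIb
DoWRKY69	Dendrobium_GLEAN_10025602	535	WRKYGQK	C-X5-C-X23-HXH	only	1	IIb
DoWRKY4	Dendrobium_GLEAN_10121280	262	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY10	Dendrobium_GLEAN_10112584	303	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY14	Dendrobium_GLEAN_10102564	316	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY26	Dendrobium_GLEAN_10089597	147	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY27	Dendrobium_GLEAN_10085956	256	WRKYGQK	C-X5-C-X23-HXH	only	1	IIc
DoWRKY40	Dendrobium_GLEAN_10073350	162	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY44	Dendrobium_GLEAN_10069083	617	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY48	Dendrobium_GLEAN_10063016	187	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY50	Dendrobium_GLEAN_10060580	158	WRKYGQK	C-X4-C-X23-HXH	only	1	IIc
DoWRKY18	Dendrobium_GLEAN_10095806	329	WRKYGQK	C-X5-C-X23-HXH	only	1	IId
DoWRKY45	Dendrobium_GLEAN_10064360	159	WRKYGQK	C-X5-C-X23-HXH	only	1	IId
DoWRKY52	Dendrobium_GLEAN_10059569	280	WRKYGQK	C-X5-C-X23-HXH	only	1	IId
DoWRKY54	Dendrobium_GLEAN_10058347	149	WRKYGQK	C-X5-C-X23-HXH	only	1	IId
DoWRKY64	Dendrobium_GLEAN_10043009	199	WRKYGQK	C-X5-C-X23-HXH	only	1	IId
DoWRKY74	Dendrobium_GLEAN_10016910	331	WRKYGQK	C-X5-C-X23-HXH	only	1	IId
DoWRKY31	Dendrobium_GLEAN_10079755	397	WRKYGQK	C-X5-C-X23-HXH	only	1	IIe
DoWRKY33	Dendrobium_GLEAN_10076351	444	WRKYGQK	C-X5-C-X23-HXH	only	1	IIe
DoWRKY35	Dendrobium_GLEAN_10075224	314	WRKYGQK	C-X5-C-X23-HXH	only	1	IIe
DoWRKY47	Dendrobium_GLEAN_10063175	396	WRKYGQK	C-X5-C-X23-HXH	only	1	IIe
DoWRKY51	Dendrobium_GLEAN_10059893	224	WRKYGQK	C-X5-C-X23-HXH	only	1	IIe
DoWRKY67	Dendrobium_GLEAN_10026080	350	WRKYGQK	C-X5-C-X23-HXH	only	1	IIe
DoWRKY3	Dendrobium_GLEAN_10121855	293	WRKYGQK	C-X3-C-X5-HXC	only	1	III
DoWRKY5	Dendrobium_GLEAN_10120404	329	WRKYGQK	C-X7-C-X23-HXC	only	1	III
DoWRKY28	Dendrobium_GLEAN_10083557	182	WRKYGEK	C-X7-C-X26-HXC	only	1	III
DoWRKY49	Dendrobium_GLEAN_10060697	274	WRKYGQK	C-X7-C-X23-HXC	only	1	III
DoWRKY55	Dendrobium_GLEAN_10054889	348	WRKYGQK	C-X7-C-X23-HXC	only	1	III
DoWRKY65	Dendrobium_GLEAN_10041878	294	WRKYGQK	C-X7-C-X23-HXC	only	1	III
DoWRKY66	Dendrobium_GLEAN_10037978	253	WRKYGQK	C-X7-C-X27-HXC	only	1	III
DoWRKY70	Dendrobium_GLEAN_10024898	365	WRKYGQK	C-X7-C-X23-HXC	only	1	III
DoWRKY75	Dendrobium_GLEAN_10014237	264	WRKYGQK	C-X7-C-X26-HXC	only	1	III
DoWRKY78	Dendrobium_GLEAN_10010985	295	WRKYGQK	C-X7-C-X23-HXC	only	1	III
DoWRKY6	Dendrobium_GLEAN_10117096	194	WRKYGRD	C-X4-C-X23-HXH	only	1	NG
DoWRKY23	Dendrobium_GLEAN_10091977	320	WRKYGQK	C-X4-C-X23-HXH	only	1	NG
DoWRKY24	Dendrobium_GLEAN_10091032	136	WRKYGKK	C-X4-C-X23-HXH	only	1	NG
DoWRKY30	Dendrobium_GLEAN_10082894	198	WRKYGKK	C-X4-C-X23-HXH	only	1	NG
DoWRKY57	Dendrobium_GLEAN_10051729	118	WKKYGQK	C-X4-C-X23-HXY	only	1	NG
DoWRKY59	Dendrobium_GLEAN_10049096	141	WNKYGQK	C-X4-C-X23-HXH	only	1	NG
DoWRKY60	Dendrobium_GLEAN_10049097	110	WTKYGQK	C-X4-C-X23-HXH	only	1	NG
DoWRKY68	Dendrobium_GLEAN_10025631	195	WRKYGKK	C-X4-C-X23-HXH	only	1	NG
DoWRKY72	Dendrobium_GLEAN_10023473	350	WRKYGQK	C-X4-C-X23-HXH	only	1	NG
DoWRKY76	Dendrobium_GLEAN_10013560	196	WRKYATN	C-X4-C-X23-HXH	only	1	NG
DoWRKY79	Dendrobium_GLEAN_10007018	196	WRKYGKK	C-X4-C-X23-HXH	only	1	NG
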