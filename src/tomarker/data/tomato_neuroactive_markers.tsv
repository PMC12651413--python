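neuroactivity	chem_class	compound	mz	rt	adduct	level	organic	variety	process
disrupting	Food additive	Amino(nitrophenyl)methylsulfonyl-propanoic acid	289.052	3.25	[M+H]+	L3	=	+	+
disrupting	Food additive	Aspartame (I)	295.1154	6.2	[M+H]+	L1	+	-	-
disrupting	Food additive	Aspartame (II)	295.1297	5.43	[M+H]+	L2	=	=	=
disrupting	Food additive	Hydroquinone	109.0296	3.97	[M-H]-	L2	=	-	+
disrupting	Industrial chemicals	1-Naphthylamine	144.0812	4.56	[M+H]+	L2	=	=	=
disrupting	Industrial chemicals	Derivative of acetaminophen	152.0709	1.58	[M+H]+	L3	=	=	-
disrupting	Industrial chemicals	Difenoconazole	406.0727	13.41	[M+H]+	L1	-	=	=
disrupting	Industrial chemicals	Methylsulfonyl(pyridin-ylmethyl)piperidinyl-pyridin	332.1436	12.07	[M+H]+	L3	=	=	=
protective	Amino Acids and Derivatives	Glutamine	147.0773	0.87	[M+H]+	L2	=	-	-
protective	Amino Acids and Derivatives	Glutamylphenylalanine	295.1299	3.70	[M+H]+	L1	=	=	=
protective	Amino Acids and Derivatives	Guanine	152.0709	1.58	[M+H]+	L1	=	=	=
protective	Amino Acids and Derivatives	Leucine-leucine (I)	245.1846	5.96	[M+H]+	L1	-	=	+
protective	Amino Acids and Derivatives	Leucine-leucine (II)	245.1867	5.91	[M+H]+	L1	-	=	+
protective	Amino Acids and Derivatives	Leucylvaline	231.1711	4.96	[M+H]+	L1	=	=	+
protective	Amino Acids and Derivatives	N-acetyltryptophan	245.0922	6.88	[M-H]-	L2	=	=	=
protective	Amino Acids and Derivatives	phenylalanine	166.0861	3.4	[M-H]-	L2	=	=	=
protective	Amino Acids and Derivatives	Tryptophan	205.0976	4.51	[M-H]-	L2	+	=	+
protective	Amino Acids and Derivatives	Tyramine	138.0902	1.95	[M-H]-	L2	=	+	=
protective	Fatty Acids and Lipids	10,16-Dihydroxypalmitic acid	287.2223	12.04	[M-H]-	L2	=	=	+
protective	Fatty Acids and Lipids	2-Isopropylmalic acid	175.0609	5.42	[M-H]-	L2	=	=	=
protective	Fatty Acids and Lipids	Elaidic/Oleic acid	281.2471	16.57	[M-H]-	L3	=	=	+
protective	Fatty Acids and Lipids	Hydroxyadipic acid	161.0453	3.6	[M-H]-	L1	=	=	-
protective	Fatty Acids and Lipids	Linoleic acid	279.2332	16.1	[M-H]-	L2	=	=	+
protective	Neurotransmitters	Adenosine	268.1041	2.59	[M+H]+	L1	=	-	+
protective	Neurotransmitters	Dopa	198.0744	2.01	[M+H]+	L1	=	=	=
protective	Neurotransmitters	Glutamic acid	148.0614	0.87	[M+H]+	L1	=	=	+
protective	Neurotransmitters	Serotonin	177.1027	2.74	[M+H]+	L1	=	+	-
protective	Neurotransmitters	Tryptamine	161.1080	4.60	[M+H]+	L2	=	+	=
protective	Neurotransmitters	Tyrosine	182.0811	1.91	[M+H]+	L1	=	=	=
protective	Nucleotides and Nucleosides	Adenine	136.0623	1.16	[M+H]+	L2	=	+	+
protective	Nucleotides and Nucleosides	Adenosine monophosphate	346.0540	1.32	[M+H]+	L2	=	+	=
protective	Nucleotides and Nucleosides	Guanosine 5'-monophosphate (I)	362.0507	1.23	[M-H]-	L2	-	+	=
protective	Nucleotides and Nucleosides	Guanosine 5'-monophosphate (II)	362.0507	1.69	[M-H]-	L2	=	+	+
protective	Nucleotides and Nucleosides	Uridine 5'-monophosphate	323.0289	1.14	[M-H]-	L2	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	5-caffeoylshikimic acid	335.0783	6.36	[M+H]+	L2	=	=	=
protective	Phenolic Compound/Polyphenols and Derivatives	Ascorbic Acid	191.0191	1.30	[M+H]+	L2	=	=	=
protective	Phenolic Compound/Polyphenols and Derivatives	Caffeic acid	179.0352	5.74	[M-H]-	L1	=	-	=
protective	Phenolic Compound/Polyphenols and Derivatives	Chlorogenic Acid	353.0878	5.27	[M-H]-	L1	=	+	=
protective	Phenolic Compound/Polyphenols and Derivatives	Citric acid	191.0189	1.31	[M-H]-	L1	=	+	+
protective	Phenolic Compound/Polyphenols and Derivatives	Crepenynic acid	277.2194	15.71	[M-H]-	L2	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Cryptochlorogenic acid	353.0886	5.34	[M-H]-	L1	=	+	=
protective	Phenolic Compound/Polyphenols and Derivatives	Dihydrocoumarin	147.0441	3.41	[M-H]-	L2	=	=	=
protective	Phenolic Compound/Polyphenols and Derivatives	Eriodictyol (I)	287.0562	8.68	[M-H]-	L2	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Eriodictyol (II)	287.0564	9.04	[M-H]-	L2	=	=	-
protective	Phenolic Compound/Polyphenols and Derivatives	Eriodictyol (III)	287.0550	6.99	[M-H]-	L3	=	+	+
protective	Phenolic Compound/Polyphenols and Derivatives	Ferulic acid	193.0500	5.14	[M-H]-	L1	=	-	-
protective	Phenolic Compound/Polyphenols and Derivatives	Feruloyltyramine	341.1390	8.72	[M-H]-	L1	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Hesperetin	301.0725	9.66	[M-H]-	L1	=	=	=
protective	Phenolic Compound/Polyphenols and Derivatives	Homoeriodictyol	301.0726	9.97	[M-H]-	L1	=	=	-
protective	Phenolic Compound/Polyphenols and Derivatives	Hydroxycinnamic acid	163.0399	2.02	[M-H]-	L1	=	-	-
protective	Phenolic Compound/Polyphenols and Derivatives	Isoquercetin	463.1240	8.06	[M-H]-	L2	=	+	+
protective	Phenolic Compound/Polyphenols and Derivatives	Malonyltryptophan	289.0828	6.90	[M-H]-	L1	=	=	=
protective	Phenolic Compound/Polyphenols and Derivatives	Naringenin	271.0607	9.58	[M-H]-	L1	=	=	-
protective	Phenolic Compound/Polyphenols and Derivatives	Naringenin chalcone	271.0639	9.51	[M-H]-	L2	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Naringin	581.1870	7.67	[M-H]-	L2	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Neochlorogenic Acid	353.0874	4.22	[M-H]-	L1	=	+	+
protective	Phenolic Compound/Polyphenols and Derivatives	Phenyllactic acid	165.0551	6.96	[M-H]-	L1	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Quercetin	301.0363	9.58	[M-H]-	L2	=	=	+
protective	Phenolic Compound/Polyphenols and Derivatives	Quinic Acid	191.0553	1.0	[M-H]-	L2	=	+	=
protective	Phenolic Compound/Polyphenols and Derivatives	Resveratrol	227.0714	7.0	[M-H]-	L3	=	=	-
protective	Phenolic Compound/Polyphenols and Derivatives	Rutin	609.1462	7.99	[M-H]-	L1	=	+	+
protective	Plant Alkaloids and Secondary Metabolites	5'-Deoxy-5'-(methylthio)adenosine	298.0973	4.73	[M+H]+	L3	+	-	+
protective	Plant Alkaloids and Secondary Metabolites	N-Caffeoyl putrescin	251.1392	4.02	[M+H]+	L3	=	+	+
protective	Plant Alkaloids and Secondary Metabolites	N-Feruloylputrescine	265.1548	5.10	[M+H]+	L2	=	=	=
protective	Plant Alkaloids and Secondary Metabolites	Sibricose A3	461.1302	3.73	[M+H]+	L2	=	-	=
protective	Plant Alkaloids and Secondary Metabolites	Tomatidinol (I)	414.3376	8.69	[M+H]+	L1	=	=	+
protective	Plant Alkaloids and Secondary Metabolites	Tomatidinol (II)	414.3376	8.86	[M+H]+	L2	=	=	+
protective	Plant Alkaloids and Secondary Metabolites	Tomatine	1034.5546	10.14	[M-H]-	L2	=	=	+
protective	Vitamins and Coenzymes	4-Pyridoxic acid	182.0455	2.72	[M-H]-	L1	=	=	=
protective	Vitamins and Coenzymes	Pantothenic Acid	220.1185	4.23	[M+H]+	L1	+	=	=
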