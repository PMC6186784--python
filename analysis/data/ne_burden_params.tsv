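id	symbol	product	length	expected_E	actual_K	published_P
c199041-189847		Type I secretion C-terminal target domain containing protein	9195	89.43	157	5.30E-11
1783631-1786309		Dolichyl-phosphate beta-D-mannosyltransferase	2679	41.25	79	8.75E-08
c436078-432929	hsdR	Type I restriction endonuclease subunit R	3150	52.46	94	1.16E-07
c1048744-1047032	hao2	Hydroxylamine oxidoreductase	1713	23.91	52	3.56E-07
c2215518-2213806	hao1	Hydroxylamine oxidoreductase	1713	23.91	52	3.56E-07
c2540363-2538651	hao3	Hydroxylamine oxidoreductase	1713	23.91	52	3.56E-07
c2076037-2074616	rbcL	Ribulose bisphosphate carboxylase large chain	1422	25.22	53	7.15E-07
c1601334-1600138		Aminotransferase	1197	22.82	49	9.90E-07
1894644-1898096		Antibiotic resistance protein VanZ	3453	50.25	87	1.33E-06
c988550-986691	ftsH	ATP-dependent metallopeptidase FtsH/Yme1/Tma family protein	1860	33.60	64	1.54E-06
amoC1	amoC1	Ammonia monooxygenase, subunit C1	816	17.69	39	6.24E-06
amoC2	amoC2	Ammonia monooxygenase, subunit C2	816	18.34	38	3.09E-05
amoC3	amoC3	Ammonia monooxygenase, subunit C3	825	15.18	36	2.98E-06
amoA1	amoA1	Ammonia monooxygenase, subunit A1	825	17.90	33	7.59E-04
amoA2	amoA2	Ammonia monooxygenase, subunit A2	825	17.90	33	7.59E-04
amoB1	amoB1	Ammonia monooxygenase, subunit B1	1263	21.48	41	9.85E-05
amoB2	amoB2	Ammonia monooxygenase, subunit B2	1263	21.48	41	9.85E-05
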