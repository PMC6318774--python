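rsid	gene	chrom	pos	ref	alt	maf	annotation
rs4244285	CYP2C19	10	96541616	G	A	0.15	CYP2C19*2 loss of function; reduced clopidogrel activation
rs4986893	CYP2C19	10	96540410	G	A	0.04	CYP2C19*3 loss of function; reduced clopidogrel activation
rs12248560	CYP2C19	10	96522463	C	T	0.21	CYP2C19*17 increased function; altered clopidogrel/antidepressant response
rs1799853	CYP2C9	10	96702047	C	T	0.11	CYP2C9*2 reduced function; warfarin dose reduction
rs1057910	CYP2C9	10	96741053	A	C	0.06	CYP2C9*3 reduced function; warfarin and phenytoin dosing
rs7900194	CYP2C9	10	96701908	G	A	0.02	CYP2C9*8 reduced function; warfarin dosing
rs9923231	VKORC1	16	31107689	C	T	0.38	VKORC1 promoter variant; warfarin sensitivity
rs9934438	VKORC1	16	31106459	G	A	0.37	VKORC1 intronic variant; warfarin sensitivity
rs3918290	DPYD	1	97915614	C	T	0.005	DPYD*2A splice defect; fluoropyrimidine toxicity
rs55886062	DPYD	1	97981343	A	C	0.005	DPYD reduced function; fluoropyrimidine toxicity
rs67376798	DPYD	1	97547947	T	A	0.007	DPYD reduced function; fluoropyrimidine toxicity
rs4149056	SLCO1B1	12	21331549	T	C	0.13	SLCO1B1*5 reduced transport; simvastatin myopathy risk
rs1800462	TPMT	6	18139228	C	G	0.005	TPMT*2 reduced function; thiopurine toxicity
rs1800460	TPMT	6	18131012	C	T	0.03	TPMT*3B reduced function; thiopurine toxicity
rs1142345	TPMT	6	18130918	T	C	0.04	TPMT*3C reduced function; thiopurine toxicity
rs116855232	NUDT15	13	48619855	C	T	0.04	NUDT15 reduced function; thiopurine toxicity
rs3745274	CYP2B6	19	41512841	G	T	0.26	CYP2B6*6 reduced function; efavirenz exposure
rs28399499	CYP2B6	19	41518221	T	C	0.02	CYP2B6*18 reduced function; efavirenz exposure
rs776746	CYP3A5	7	99672916	T	C	0.30	CYP3A5*3 loss of function; tacrolimus dosing
rs4148323	UGT1A1	2	234669144	G	A	0.08	UGT1A1*6 reduced function; irinotecan toxicity
rs887829	UGT1A1	2	234668570	C	T	0.33	UGT1A1*80; atazanavir hyperbilirubinemia
rs12979860	IFNL3	19	39738787	C	T	0.32	IFNL3 genotype; peginterferon response
rs8099917	IFNL3	19	39743165	T	G	0.20	IFNL3/IFNL4 region; peginterferon response
rs3892097	CYP2D6	22	42524947	C	T	0.12	CYP2D6*4 loss of function; tricyclic/opioid metabolism
rs1065852	CYP2D6	22	42526694	G	A	0.22	CYP2D6*10 reduced function; tricyclic metabolism
rs5030655	CYP2D6	22	42525086	TA	T	0.01	CYP2D6*6 loss of function; tricyclic/opioid metabolism
rs2231142	ABCG2	4	89052323	G	T	0.12	ABCG2 Q141K; rosuvastatin exposure
rs1801133	MTHFR	1	11856378	G	A	0.31	MTHFR C677T; methotrexate toxicity risk
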