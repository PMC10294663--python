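ko_id	locus	gene_name	reg_type	function	is_sporulation
K01356	BSU_17850	lexA	R	LexA repressor	true
K03086	BSU_25200	sigA	R	RNA polymerase sigma factor RpoD	true
K03091	BSU_00980	sigH	R	RNA polymerase sigma-H factor	true
	BSU_15320	sigE	R	RNA polymerase sigma-E factor	true
	BSU_15330	sigG	R	RNA polymerase sigma-G factor	true
	BSU_23450	sigF	R	RNA polymerase sigma-F factor	true
	CD630_07720	sigF	R	RNA polymerase sigma-F factor	true
	CD630_12300	sigK	R	RNA polymerase sigma-K factor	true
	CD630_26420	sigG	R	RNA polymerase sigma-G factor	true
	CD630_26430	sigE	R	RNA polymerase sigma-E factor	true
K04769	BSU_560	spoVT	R	Stage V sporulation protein T	true
	CD630_34990	spoVT	R	Stage V sporulation protein T	true
K06283	BSU_36420	spoIIID	R	Stage III sporulation protein D	true
	CD630_1260	spoIIID	R	Stage III sporulation protein D	true
K06284	BSU_370	abrB	R	Transition state regulatory protein AbrB	true
K07699	BSU_24220	spo0A	R	Stage 0 sporulation protein A	true
	CD630_12140	spo0A	R	Stage 0 sporulation protein A	true
K07738	CD630_26400	nrdR	R	Transcriptional regulator, repressor NrdR family	true
K03496	BSU_40970	parA	R+NR	Sporulation initiation inhibitor protein Soj	true
	CD630_36720	soj	R+NR	Transcriptional regulator, sporulation initiation inhibitor, chromosome partitioning protein	true
K00390	BSU_10930	yitB	NR	Phosphoadenosine phosphosulfate reductase	true
K00640	CD630_15950	cysE	NR	Serine acetyltransferase (SAT)	true
K00820	CD630_1200	glmS	NR	Glucosamine-fructose-6-phosphate aminotransferase (isomerizing)	true
K00974	BSU_22450	cca	NR	CCA-adding enzyme	true
K01142	BSU_40880	exoA	NR	Exodeoxyribonuclease, repair of oxidative DNA damage in spores	true
K01449	BSU_02600	cwlJ	NR	Cell wall hydrolase CwlJ	true
	BSU_22930	sleB	NR	Spore cortex-lytic enzyme	true
	CD630_35630	NA	NR	Putative spore cortex-lytic hydrolase	true
K02049	BSU_30610	ytlC	NR	ABC transporter ATP-binding protein	true
K02343	CD630_160	dnaX	NR	DNA polymerase III subunits gamma and tau	true
K03466	BSU_16800	spoIIIE	NR	Spore DNA translocase	true
K03497	BSU_40960	parB	NR	Stage 0 sporulation protein J	true
	CD630_36710	spo0J	NR	Stage 0 sporulation protein J, site-specific DNA-binding protein	true
K03657	CD630_7490	NA	NR	Putative DNA helicase, UvrD/REP type	true
K03664	BSU_33600	smpB	NR	SsrA-binding protein	true
K03698	BSU_9930	yhaM	NR	3'-5' exoribonuclease YhaM	true
K06381	BSU_36750	spoIID	NR	Stage II sporulation protein D	true
	CD630_1240	spoIID	NR	Stage II sporulation protein D	true
K06412	BSU_490	spoVG	NR	Septation protein SpoVG	true
	CD630_35160	spoVG	NR	Regulator required for spore cortex synthesis	true
K07171	CD630_34610	endoA	NR	Endoribonuclease toxin	true
K10716	BSU_31322	yugO	NR	Potassium channel protein YugO	true
K10979	BSU_13410	ykoV	NR	DNA repair protein YkoV	true
K014487	BSU_17410	cwlC	NR	Mother cell lysis	true
	BSU_01530	cwlD	NR	Spore cortex peptidoglycan synthesis	true
K02647	BSU_28670	ysfB	U	Hypothetical protein; similar to carbohydrate diacid transcriptional activator	true
K03469	BSU_21970	ypeP	U	Hypothetical protein; similar to RNase HI	true
K07175	BSU_14810	ylaK	U	Hypothetical protein; similar to PhoH	true
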