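id	species	aligned_sequence	printed_mass	printed_charge	printed_pI	approach
cC1a	Coffea canephora	ZEGECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CVGNC	3873.1	-3	4.00	T,P
cC1b	Coffea canephora	-EGECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CVGNC	3764.3	-3	4.00	T,P
cC1c	Coffea canephora	--GECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CVGNC	3633.4	-2	4.14	T,P
cC2	Coffea canephora	QEGECSPFGKPCRYNPWGCCDSCVCVAT-PADE-GRCLGNC	4145.6	-2	4.51	T
cC3	Coffea canephora	QEGECSPLGKPCKYNPWGCCGSCLCIVDQP-THEGTCVGNC	4206.7	-2	4.83	T
cC4	Coffea canephora	QEGECSPLGKPCRYNPWGCCGSCLCIVDQP-THEGTCVGNC	4234.7	-2	4.83	T
cC5	Coffea canephora	QEGECSALGKPCRYNPSGCCGLCVCVIPDPTDE-GSCIGIC	4067.7	-3	4.18	T
cC6	Coffea canephora	QEVECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CVGNC	3931.6	-3	4.00	T
cC7	Coffea canephora	QEPSCIPVLGSCVGNPWGCCPGCMCIRQ-LTDR---CHGYC	3976.6	0	6.69	T
cL1a	Coffea liberica	ZEGECSPAGKPCR--PLGCCGACLCIVDHP-THEGTCVGNC	3819.2	-2	5.36	T,P
cL1b	Coffea liberica	-EGECSPAGKPCR--PLGCCGACLCIVDHP-THEGTCVGNC	3708.2	-2	5.36	T,P
cL1c	Coffea liberica	--GECSPAGKPCR--PLGCCGACLCIVDHP-THEGTCVGNC	3579.1	-1	6.01	T,P
cL2	Coffea liberica	--GECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CIGNC	3649.2	-2	4.14	T,P
cL3	Coffea liberica	GKDTCIGLLESCKDDPWGCCFGCVCLWP--GDL---CRGSC	3834.4	-2	4.36	T
cL4	Coffea liberica	QEGECSPAGKSCR--PVRCCDFCVCVVDYP-THVGTCRGNC	4069.7	-2	4.36	T
cL5	Coffea liberica	QEGECSPAGKPCR--PVRCCDFCVCVVDYP-THVGTCRGNC	4082.7	0	6.70	T
cL6	Coffea liberica	QEPSCIPVLGSCVGNPWGCCPGCMCIRQ-LTDR---CHGYC	3976.7	0	6.69	T
cA1	Coffea arabica	QEGECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CIGNC	3903.5	-3	4.00	T
cA2	Coffea arabica	QEGECSPLGEACAGNPWGCCPGCICIWQ-LTDR---CVGNC	3863.5	-3	4.00	T
cA3	Coffea arabica	QEPSCLPAGESCTGNPWGCCPGCICIWQ-LTER---CVGNC	3905.6	-2	4.25	T
cA4	Coffea arabica	QEPSCIPVGEPCAGNPGGCCDGCICIWQ-LTDR---CAGSC	3733.5	-3	3.92	T
cA5	Coffea arabica	QEGECSPLGKPCRYNPRGCCDFCVCVVADVTDEEGSCRGNC	4389.7	-3	4.44	T
cA6	Coffea arabica	RKDTCIGLLESCKDDPYGCCPGCVCLWP--GDL---CRGDC	3884.6	-2	4.46	T
cA7	Coffea arabica	QEGECSPAGKPCR--PVRCCDSCLCIVDYP-THVGTCRGNC	4047.7	0	6.70	T
cA8	Coffea arabica	QEGECSPLGKPCAGNPWGCCPGCICIWQ-LTDR---CIGNC	3902.5	-1	4.68	T
cA9	Coffea arabica	QEPSCIPVGEPCAGNPGGCCDGCICIWQ-LTDR---CAGSC	3733.3	-3	3.92	T
cA10	Coffea arabica	QEGECSPLGEPCAGNPWGCCPGCICIWQ-LTDR---CVGNC	3890.1	-3	4.00	T
cR1	Coffea racemosa	QEPRCIPALGSCVGNPWGCCFGCMCIRQ-LTDR---CLGYC	4043.7	+1	7.70	T
cR2	Coffea racemosa	QEPRCIPVFGSCVGNPWGCCFGCMCIRQ-HTNR---CLGYC	4128.7	+2	8.22	T
cR3	Coffea racemosa	QEGECSPFGKPCRYNPWGCCGSCLCVVDHP-THEGTCVGNC	4263.7	-2	5.36	T
cR4	Coffea racemosa	QEGECSPFGKPCRYNPWGCCGSCVCVVDHP-THEGTCLGNC	4263.7	-2	5.36	T
cR5	Coffea racemosa	QEGKCSPAGKPC--DPWGCCDFCVCVVDFPGGE-GRCAGNC	3885.5	-2	4.44	T
cR6	Coffea racemosa	QEEKCSPAGKPCRYNPRGCCDFCVCVVDFPGGE-GSCLGNC	4218.7	-1	4.94	T
cR7	Coffea racemosa	GKDTCIGLLESCKDDPWGCCPGCVCLWP--GDL---CRGSC	3780.5	-2	4.36	T
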