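marker_id	chrom	pos	allele_a	allele_b	line0001	line0002	line0003	line0004	line0005	line0006	line0007	line0008	line0009	line0010	line0011	line0012	line0013	line0014	line0015	line0016	line0017	line0018	line0019	line0020	line0021	line0022	line0023	line0024	line0025	line0026	line0027	line0028	line0029	line0030	line0031	line0032	line0033	line0034	line0035	line0036	line0037	line0038	line0039	line0040	line0041	line0042	line0043	line0044	line0045	line0046	line0047	line0048	line0049	line0050	line0051	line0052	line0053	line0054	line0055	line0056	line0057	line0058	line0059	line0060
causal	1	1000	A	B	2	0	2	2	0	2	2	2	0	0	0	2	2	2	0	0	2	0	2	2	2	0	2	2	2	0	0	0	0	2	2	2	0	0	0	0	0	0	0	2	0	2	2	0	2	2	0	0	2	0	0	0	2	2	2	2	0	2	0	0
null00001	1	2000	A	B	0	0	2	0	0	0	0	0	0	0	0	2	0	0	0	0	2	0	2	2	0	2	0	0	0	2	0	0	0	0	2	0	0	0	0	0	0	0	2	2	2	0	2	2	2	0	0	0	2	0	0	0	0	0	2	2	2	0	0	0
null00002	1	3000	A	B	0	0	0	0	0	0	0	0	0	2	0	0	0	0	2	0	2	0	0	0	2	0	0	0	0	0	0	0	2	2	0	0	0	2	0	2	2	2	0	2	0	0	0	0	2	2	0	2	0	0	0	2	0	0	0	2	2	2	2	2
null00003	1	4000	A	B	0	2	2	0	0	2	0	2	0	0	2	0	0	2	2	0	0	2	2	0	0	0	0	0	2	0	0	2	2	0	2	2	2	0	0	2	0	0	0	2	2	0	2	0	2	2	0	0	0	2	2	2	2	0	2	0	0	2	2	0
null00004	1	5000	A	B	2	2	2	0	0	0	2	2	0	0	0	2	2	0	0	2	0	2	0	0	2	0	0	0	0	0	0	0	0	2	2	0	0	0	2	2	0	0	0	0	2	0	0	0	0	0	2	0	2	0	2	2	2	2	2	2	2	0	2	0
null00005	1	6000	A	B	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	2	0	0	0	2	0	0	0	0	0	0	0	0	2	0	0	0	0	0	2	0	2	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0
null00006	1	7000	A	B	2	2	0	2	2	0	0	0	0	0	2	2	0	2	2	2	2	2	0	2	2	2	0	2	2	0	2	2	0	2	2	0	2	2	0	2	2	0	2	2	0	2	0	2	2	2	0	2	0	0	0	2	0	2	2	0	0	0	2	2
null00007	1	8000	A	B	2	0	2	2	2	2	2	0	0	0	2	2	2	2	0	2	0	2	2	2	2	0	2	0	2	2	0	0	0	2	2	2	2	2	0	2	2	2	2	2	2	0	2	2	2	0	0	2	2	2	2	2	2	2	0	2	2	0	2	2
null00008	1	9000	A	B	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	0	2	0	2	2	0	2	2	0	2	2	2	0	2	0	2	2	2	2	2	2	2	2	2	0	0	2	0	0	2	2	2	2	2	0	2	2	0
null00009	1	10000	A	B	0	0	0	0	2	0	0	0	0	0	0	0	0	2	0	0	0	2	0	0	0	0	2	0	2	2	0	2	0	2	0	0	0	0	0	2	0	0	0	0	0	2	0	0	0	0	0	0	0	2	0	0	2	2	0	2	2	2	0	2
null00010	1	11000	A	B	2	2	2	2	0	2	2	0	0	0	2	2	2	2	2	0	2	0	2	2	2	2	0	0	0	0	2	2	2	2	2	2	0	0	2	2	0	2	2	0	0	2	2	0	2	0	2	0	2	0	0	2	0	0	0	2	2	2	0	0
null00011	1	12000	A	B	2	2	2	2	2	2	2	0	2	0	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	2	2	0	2	0	0	2	0	2	2	2
null00012	1	13000	A	B	2	2	0	2	2	2	2	2	0	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	2	0	2	2	0	2	0	2	2	2	2	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2
null00013	1	14000	A	B	0	0	2	0	0	2	2	2	0	2	2	0	0	2	0	2	2	0	0	2	2	0	2	2	2	2	0	0	2	0	2	2	0	2	0	2	0	2	2	2	2	2	2	2	2	2	2	0	2	2	2	0	2	2	2	0	2	0	0	2
null00014	1	15000	A	B	0	0	0	2	0	0	0	0	0	0	0	2	0	0	0	0	0	0	2	0	0	2	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	2	0	0	0	2	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	2	2	2
null00015	1	16000	A	B	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	2	0	2	0	0	0	0	0	0	0	0
null00016	1	17000	A	B	0	0	0	0	2	2	2	0	0	2	0	0	0	2	2	2	2	0	2	0	2	0	2	0	0	0	0	0	2	0	2	0	2	0	2	2	0	2	0	0	2	2	0	0	2	2	2	0	2	0	2	0	2	0	0	2	0	2	0	2
null00017	1	18000	A	B	2	2	0	0	2	2	2	0	0	0	2	2	0	2	0	0	0	0	2	2	0	2	2	2	2	0	2	0	2	2	2	0	2	2	2	2	2	2	0	2	2	2	0	0	2	2	2	2	2	2	2	2	2	0	2	0	0	2	2	0
null00018	1	19000	A	B	2	0	0	0	2	2	0	0	0	0	2	0	0	0	0	2	2	0	0	2	0	2	0	0	2	0	0	0	0	0	0	2	2	0	0	0	2	0	0	0	0	0	0	2	2	2	0	0	0	2	0	2	0	2	0	0	0	0	0	0
null00019	1	20000	A	B	2	0	2	2	0	0	2	2	2	2	0	0	2	0	2	2	2	2	0	0	0	2	0	0	0	0	2	0	2	0	2	2	0	2	2	2	0	0	2	0	2	2	2	2	2	0	0	2	2	0	0	2	2	2	0	0	2	0	2	2
null00020	2	1000	A	B	0	2	2	2	2	2	2	2	2	0	2	2	2	2	2	0	2	2	2	2	2	2	2	0	2	2	2	2	2	2	0	0	2	2	2	2	2	2	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2
null00021	2	2000	A	B	2	2	2	2	2	2	0	2	2	2	2	2	0	0	2	0	0	2	2	0	2	2	0	2	2	2	2	0	2	2	2	2	0	0	2	2	0	2	2	2	2	0	2	0	2	2	2	0	0	2	2	2	2	2	2	0	2	2	2	0
null00022	2	3000	A	B	0	0	2	0	0	0	0	0	2	2	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	2	2	0	0	2	0	0	0	0	0	2	2	0	0	0	2	0	2	2	0	0	2	0	0	2	0	0	0	0
null00023	2	4000	A	B	0	0	0	2	0	0	0	0	2	0	2	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	2	0	0	2	2	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	2	0	0	0	0
null00024	2	5000	A	B	2	2	2	0	2	0	2	0	0	2	2	2	2	2	2	2	2	0	2	0	2	0	2	2	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	0	0	2	2	2	0	0	2	0	0	0	2	2	2
null00025	2	6000	A	B	0	0	0	0	0	0	0	0	2	0	0	2	2	2	0	2	0	0	0	0	0	0	2	0	0	0	0	0	0	0	2	2	0	0	2	2	0	2	2	2	0	0	0	0	0	0	0	0	2	0	0	2	2	2	2	2	0	0	0	0
null00026	2	7000	A	B	0	0	0	0	0	0	2	0	0	0	0	0	0	0	2	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	2	0	0	0	0	0	0	0	0
null00027	2	8000	A	B	2	2	2	0	0	0	0	2	2	0	2	2	0	0	2	2	0	2	2	2	0	0	2	0	2	2	0	2	2	2	2	2	2	2	2	2	0	0	0	2	2	2	2	2	2	0	2	2	2	0	2	2	2	2	2	2	2	2	2	0
null00028	2	9000	A	B	2	0	2	0	2	2	0	2	0	2	2	2	0	0	2	2	2	0	0	2	0	0	2	0	2	0	2	2	2	0	2	2	0	0	0	2	2	2	2	2	2	2	2	0	2	2	0	2	0	2	2	2	0	0	0	0	0	0	2	0
null00029	2	10000	A	B	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	2	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	2	0	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	2
null00030	2	11000	A	B	0	2	0	0	0	0	0	0	2	2	0	2	0	2	0	2	0	2	0	2	0	2	2	2	2	2	0	0	0	0	2	2	2	2	2	2	2	0	2	2	0	0	2	2	2	2	0	0	2	2	2	2	0	2	0	0	0	0	2	0
null00031	2	12000	A	B	2	2	0	2	0	2	2	0	0	2	0	2	0	2	2	2	0	2	2	0	0	2	2	0	0	2	2	2	2	2	2	2	2	0	0	2	2	0	2	2	2	2	2	2	0	2	2	0	0	0	2	2	0	2	2	0	2	0	2	2
null00032	2	13000	A	B	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2
null00033	2	14000	A	B	2	2	2	2	0	2	2	2	0	0	2	2	2	2	2	2	2	0	2	2	2	0	2	2	0	2	2	2	2	2	2	2	0	2	2	0	2	2	0	2	2	2	2	2	2	0	0	2	2	2	0	2	2	2	2	2	2	2	2	2
null00034	2	15000	A	B	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	2	0	0	0	0	0	0	0	0	2	0	0	0	2	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	2
null00035	2	16000	A	B	2	0	2	2	2	2	0	2	2	0	2	0	2	2	0	2	0	2	2	2	2	0	0	0	0	0	0	0	0	2	0	2	0	0	0	0	0	0	0	0	2	0	2	0	2	2	2	2	0	2	0	2	2	0	2	0	2	2	0	2
null00036	2	17000	A	B	0	0	0	0	0	2	2	0	0	0	0	0	0	0	2	0	2	0	2	0	0	2	2	0	0	0	0	0	2	0	0	0	0	0	0	0	0	2	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0
null00037	2	18000	A	B	0	0	0	0	2	0	0	0	0	0	0	0	2	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	2	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	2	2	0	0	0	0	0	0
null00038	2	19000	A	B	0	2	0	0	0	0	0	2	0	0	0	0	0	0	2	0	0	0	2	0	0	0	0	0	0	0	0	0	2	2	0	0	0	2	0	0	0	2	0	0	2	0	2	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	2	0
null00039	2	20000	A	B	2	2	2	0	0	0	2	2	0	2	0	2	2	2	0	2	2	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	2	0	2	2	0	2	0	2	2	0	2	2	0	2	2	2	2	2	2	2	2	2	2	2	2
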