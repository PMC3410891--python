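accession_id	trait1	trait2
line0001	0.2325071885354905	0.345584192064786
line0002	-0.9804227992347663	0.8216181435011584
line0003	1.3589546200482243	0.33043707618338714
line0004	-2.1898318221295323	NA
line0005	0.15439963842408286	0.9053558666731177
line0006	-1.0311957371132396	0.4463745723640113
line0007	-1.4397589286504477	-0.5369532353602852
line0008	-0.3628650256195353	0.5811181041963531
line0009	-0.09164877821362992	0.36457239618607573
line0010	-0.3221041251932241	0.294132496655526
line0011	0.29435163910757534	0.02842224131579679
line0012	-0.3691040676882507	0.5467129866124469
line0013	1.7702863075077329	-0.7364540870016669
line0014	0.7217597484652192	-0.16290994799305278
line0015	-0.348778603298154	-0.48211931267997826
line0016	-0.43296994191614296	0.5988462126346276
line0017	-2.171244448571158	0.03972210748165899
line0018	0.1453665889334112	-0.2924567509650886
line0019	-0.23188132087703722	-0.7819084623568421
line0020	-3.2582932920952716	-0.2571922406188707
line0021	-0.5035723091541002	0.008142180518343508
line0022	-0.450517014627476	-0.2756029052993704
line0023	2.6635163882559905	1.2940638143982073
line0024	-2.2541679178399647	1.0067243153057943
line0025	-1.8620261996010805	-2.7111624789659685
line0026	0.5549848215528499	-1.8890132459676727
line0027	0.6783815787319816	-0.17477209205516195
line0028	-0.37249146936282074	-0.42219041157635356
line0029	-0.31604291140445545	0.2136429974986111
line0030	1.2243530948299692	0.21732193102256359
line0031	-3.1906496954179655	2.1178387550510482
line0032	-2.4917905267583342	-1.1120207626922813
line0033	-0.14036670042535593	-0.37760500712699807
line0034	0.774945283064563	2.0427716074923303
line0035	-0.2178650440833698	0.6467029962018469
line0036	0.05046839586757731	0.6630633723762617
line0037	0.566894636282006	-0.5140063716874629
line0038	1.053442366639073	-1.6480751708556527
line0039	-0.2884242365741563	0.16746474422274113
line0040	0.27474491439986093	0.10901408782154753
line0041	0.9110276106714212	-1.2273520542445742
line0042	-1.9832989127871425	-0.6832266617805622
line0043	1.8413716058307326	-0.07204367972722743
line0044	-0.5091577661806291	-0.9447516230607774
line0045	0.4537085506547351	-0.09826996785221727
line0046	-0.06392857110041139	0.09548302746945433
line0047	-0.47900580035061463	0.03558623705548571
line0048	-0.49155096382913754	-0.5062916583143148
line0049	0.7146215463806318	0.5937480717858228
line0050	0.49776966408134105	0.8911669542823284
line0051	-0.0648681015942516	0.3208483045665637
line0052	0.035056579366608186	-0.818230227390307
line0053	1.1567610994365707	0.7316522837854408
line0054	-1.1574281595194398	-0.5014400184670523
line0055	1.4095387626193845	0.8791606182879853
line0056	1.5290146455896205	-1.0717874168774442
line0057	1.301813149375205	0.9144672031287812
line0058	-0.2641562858393734	-0.02006345461548042
line0059	-0.2290409008340638	-1.2487488903344155
line0060	0.38448293578687276	-0.31389947196684775
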