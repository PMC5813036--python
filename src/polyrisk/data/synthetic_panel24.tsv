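rsid	chrom	beta	freq	source
rs91001	1	0.0823	0.737	BPC3
rs91002	2	0.0447	0.306	BPC3
rs91003	3	0.0633	0.592	BPC3
rs91004	4	0.0585	0.376	BPC3
rs91005	5	0.1065	0.142	BPC3
rs91006	6	0.0884	0.296	BPC3
rs91007	7	0.0469	0.637	BPC3
rs91008	8	0.1277	0.498	BPC3
rs91009	9	0.0478	0.106	BPC3
rs91010	10	0.1321	0.374	BPC3
rs999737	14	0.0668	0.538	BPC3
rs91012	12	0.1253	0.547	BPC3
rs91013	13	0.0927	0.104	BPC3
rs91014	14	0.0654	0.568	BPC3
rs91015	15	0.106	0.761	BPC3
rs91016	16	0.1075	0.143	BPC3
rs91017	17	0.0345	0.603	BPC3
rs91018	18	0.0719	0.696	BPC3
rs91019	19	0.0394	0.734	BPC3
rs91020	20	0.0559	0.275	BPC3
rs91021	21	0.0404	0.569	BPC3
rs91022	22	0.0365	0.587	BPC3
rs91023	1	0.04	0.801	BPC3
rs10483813	14	0.0668	0.558	BPC3
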