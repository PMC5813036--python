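rsid	chrom	beta	freq	source
rs6678914	1	0.0392	0.129	BCAC-COGS
rs92002	2	0.1005	0.829	BCAC-COGS
rs92003	3	0.0997	0.132	BCAC-COGS
rs92004	4	0.0378	0.73	BCAC-COGS
rs92005	5	0.0449	0.873	BCAC-COGS
rs92006	6	0.0591	0.879	BCAC-COGS
rs92007	7	0.0385	0.745	BCAC-COGS
rs92008	8	0.0805	0.149	BCAC-COGS
rs92009	9	0.0514	0.122	BCAC-COGS
rs92010	10	0.028	0.419	BCAC-COGS
rs92011	11	0.0946	0.346	BCAC-COGS
rs92012	12	0.0419	0.778	BCAC-COGS
rs92013	13	0.094	0.568	BCAC-COGS
rs92014	14	0.0598	0.884	BCAC-COGS
rs92015	15	0.0519	0.59	BCAC-COGS
rs92016	16	0.0384	0.463	BCAC-COGS
rs92017	17	0.0796	0.513	BCAC-COGS
rs92018	18	0.0881	0.614	BCAC-COGS
rs92019	19	0.0461	0.657	BCAC-COGS
rs92020	20	0.0544	0.343	BCAC-COGS
rs92021	21	0.0612	0.636	BCAC-COGS
rs92022	22	0.096	0.754	BCAC-COGS
rs4245739	1	0.0662	0.575	BCAC-COGS
rs92024	2	0.0774	0.373	BCAC-COGS
rs92025	3	0.083	0.328	BCAC-COGS
rs92026	4	0.0272	0.252	BCAC-COGS
rs92027	5	0.068	0.227	BCAC-COGS
rs92028	6	0.0466	0.212	BCAC-COGS
rs92029	7	0.1029	0.135	BCAC-COGS
rs92030	8	0.0541	0.722	BCAC-COGS
rs92031	9	0.0795	0.261	BCAC-COGS
rs92032	10	0.0494	0.545	BCAC-COGS
rs92033	11	0.0463	0.112	BCAC-COGS
rs92034	12	0.0856	0.662	BCAC-COGS
rs92035	13	0.0313	0.642	BCAC-COGS
rs92036	14	0.0899	0.754	BCAC-COGS
rs92037	15	0.08	0.288	BCAC-COGS
rs92038	16	0.0375	0.173	BCAC-COGS
rs92039	17	0.0977	0.889	BCAC-COGS
rs92040	18	0.0439	0.143	BCAC-COGS
rs92041	19	0.0404	0.178	BCAC-COGS
rs92042	20	0.073	0.577	BCAC-COGS
rs92043	21	0.0521	0.346	BCAC-COGS
rs92044	22	0.0881	0.498	BCAC-COGS
rs92045	1	0.0541	0.376	BCAC-COGS
rs92046	2	0.0364	0.88	BCAC-COGS
rs92047	3	0.0278	0.51	BCAC-COGS
rs92048	4	0.0743	0.146	BCAC-COGS
rs92049	5	0.034	0.45	BCAC-COGS
rs92050	6	0.0712	0.53	BCAC-COGS
rs92051	7	0.0338	0.306	BCAC-COGS
rs92052	8	0.0601	0.811	BCAC-COGS
rs92053	9	0.0793	0.102	BCAC-COGS
rs92054	10	0.0317	0.73	BCAC-COGS
rs92055	11	0.0971	0.863	BCAC-COGS
rs92056	12	0.0422	0.17	BCAC-COGS
rs92057	13	0.0483	0.452	BCAC-COGS
rs92058	14	0.0372	0.337	BCAC-COGS
rs92059	15	0.079	0.103	BCAC-COGS
rs92060	16	0.0911	0.429	BCAC-COGS
rs92061	17	0.0645	0.672	BCAC-COGS
rs92062	18	0.0885	0.615	BCAC-COGS
rs92063	19	0.0841	0.257	BCAC-COGS
rs92064	20	0.0807	0.546	BCAC-COGS
rs92065	21	0.0695	0.521	BCAC-COGS
rs92066	22	0.0276	0.661	BCAC-COGS
rs92067	1	0.0359	0.606	BCAC-COGS
rs92068	2	0.0762	0.454	BCAC-COGS
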