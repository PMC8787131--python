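mirna_id	mirna_name	mirna_fc	mirna_fdr	mirna_regulation	target_id	target_symbol	target_fc_abs	target_fdr	target_regulation
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001033407	Gm815	1.521011	0.04507730	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_010738	Ly6a	1.621894	0.03735421	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001163350	Ntng1	1.795526	0.04875637	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001025568	Pde1c	1.544196	0.04748477	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_198932	Pou2f1	1.5370071	0.04118802	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_009152	Sema3a	2.5020425	0.04096039	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_177164	Vwc2l	1.8152527	0.02411733	Down
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_145575	Cald1	1.602462	0.04895628	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001037321	Fbxo40	1.5813568	0.02854253	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_010262	Gbx2	2.0050368	0.04074322	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_010418	Herc2	1.6062031	0.04839108	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_026348	Itgb3bp	1.5665871	0.00909908	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001098404	Nr1i2	1.7842534	0.04952551	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_133752	Opa1	1.6633599	0.03013054	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001003717	Osbpl8	1.6370533	0.04842034	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_028748	Paqr5	1.7612659	0.02971225	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001159367	Per1	1.567625	0.02170788	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_011137	Pou2f1	1.5176835	0.02779596	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_178227	Scn3b	1.6376927	0.02688412	Up
42519	mmu-miR-465c-5p	1.532561563	0.049692	Up	NM_001113404	Tshr	1.7740262	0.03473434	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_009649	Akap2	1.522913	0.04842372	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_172595	Arl15	1.5095077	0.04860469	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_029933	Bcl9	1.5354732	0.02891231	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_001081225	Fam178a	1.6083025	0.04959859	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_030201	Hspa13	3.1505609	0.01178443	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_011365	Itsn2	1.7630032	0.03734254	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_178227	Scn3b	1.6376927	0.02688412	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_173010	Ube3a	1.6787672	0.01200062	Up
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_001109691	Phf21a	1.859211	0.03746215	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_011081	Piga	1.6523745	0.04463066	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_009152	Sema3a	2.5020425	0.04096039	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_011349	Sema3f	1.7213542	0.04393336	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_001199205	Spag9	1.517349	0.04762527	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_029056	Tdrd9	1.5761601	0.04880729	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_001101640	Tmem207	1.8919897	0.04882137	Down
147186	mmu-miR-200b-3p	0.658253975	0.041228	down	NM_011909	Usp18	2.5167851	0.02862872	Down
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_009622	Adcy1	1.580024	0.03985197	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_172595	Arl15	1.5095077	0.04860469	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_001163333	Cttnbp2nl	1.7116936	0.01972822	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_152895	Kdm5b	1.687644	0.04898798	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_001139509	Nr4a2	1.9803841	0.04820689	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_133752	Opa1	1.6633599	0.03013054	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_009364	Tfpi2	1.9140846	0.04680254	Up
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_009625	Adcyap1	1.6437125	0.03973875	Down
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_009152	Sema3a	2.5020425	0.04096039	Down
42883	mmu-miR-883b-3p	0.569539569	0.039109	Down	NM_001039967	Zfp869	1.7256061	0.02157675	Down
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_021483	Pex5l	1.618897	0.03024903	Up
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_011382	Six4	1.510553	0.04898937	Up
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_177829	Spink10	1.535757	0.02555243	Up
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_001102425	Stx16	1.6225739	0.04827980	Up
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_173010	Ube3a	1.6787672	0.01200062	Up
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_019626	Cbln1	2.1865587	0.03002855	Down
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_001164518	Iglon5	1.9751669	0.02888774	Down
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_001025568	Pde1c	1.544196	0.04748477	Down
11091	mmu-miR-377-3p	0.471786427	0.066332*	down	NM_001109691	Phf21a	1.859211	0.03746215	Down
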