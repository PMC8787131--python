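mirna_id	mirna_name	mirna_fc	mirna_fdr	mirna_regulation	target_id	target_symbol	target_fc_abs	target_fdr	target_regulation
147186	mmu-miR-200b-3p	0.658254	0.041228	Down	ENSMUST00000159119	Gas5	2.3057933	0.04911062	Down
42883	mmu-miR-883b-3p	0.56954	0.039109	Down	ENSMUST00000148977	4930417H01Rik	1.6698261	0.04292526	Up
42883	mmu-miR-883b-3p	0.56954	0.039109	Down	ENSMUST00000160227	AI480526	1.9144645	0.03374033	Up
11091	mmu-miR-377-3p	0.471786	0.066332*	Down	ENSMUST00000126472	5930412G12Rik	1.8078425	0.03637584	Up
11091	mmu-miR-377-3p	0.471786	0.066332*	Down	ENSMUST00000165938	6430628N08Rik	1.5305915	0.04965351	Up
11091	mmu-miR-377-3p	0.471786	0.066332*	Down	NR_015500	A530013C23Rik	2.0565884	0.04294613	Up
11091	mmu-miR-377-3p	0.471786	0.066332*	Down	ENSMUST00000155013	A930007I19Rik	1.5199345	0.04227756	Up
11091	mmu-miR-377-3p	0.471786	0.066332*	Down	ENSMUST00000132811	Gm15489	2.6704226	0.04533299	Up
11091	mmu-miR-377-3p	0.471786	0.066332*	Down	ENSMUST00000162649	Gm16251	1.9383893	0.04966378	Up
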