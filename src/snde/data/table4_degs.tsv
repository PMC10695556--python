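Cell	logFC	logCPM	LR	p-Value	adj_pval	ensembl_id	HGNC
OPC	-4.1544663	4.92100803	21.6911445	3.20E-06	0.04985906	ENSG00000166573	GALR1
Astro	-4.5845276	4.7965143	22.2367847	2.41E-06	0.037634	ENSG00000137959	IFI44L
Micro	-3.7616619	7.32875316	26.8149688	2.24E-07	0.00077905	ENSG00000077238	IL4R
Micro	-2.0681446	7.88736441	17.5929095	2.74E-05	0.0346187	ENSG00000105835	NAMPT
Micro	-1.6757556	7.58472506	19.1736829	1.19E-05	0.02076348	ENSG00000118257	NRP2
Micro	-3.1556403	6.85232653	19.2064627	1.17E-05	0.02076348	ENSG00000135363	LMO2
Micro	-3.4339265	6.9290472	19.5975589	9.56E-06	0.02076348	ENSG00000138135	CH25H
Micro	-2.8183109	6.77500676	16.907959	3.92E-05	0.04550806	ENSG00000142408	CACNG8
Micro	2.90076647	8.34560617	45.5144266	1.52E-11	2.11E-07	ENSG00000144724	PTPRG
Micro	3.25867589	6.91671013	16.5519147	4.73E-05	0.0490155	ENSG00000163106	HPGDS
Micro	-2.0290905	7.12321166	16.4746746	4.93E-05	0.0490155	ENSG00000171612	SLC25A33
Micro	-3.4657301	6.93307221	19.7883301	8.65E-06	0.02076348	ENSG00000172243	CLEC7A
Micro	-4.172807	7.16813583	34.3515807	4.60E-09	3.20E-05	ENSG00000174600	CMKLR1
Micro	-3.1984588	6.87310555	18.5335889	1.67E-05	0.0232342	ENSG00000227531	RP11-202G18.1
Micro	3.40562887	6.9381703	18.5526502	1.65E-05	0.0232342	ENSG00000228058	RP11-552D4.1
Micro	4.46073301	7.66559163	29.7716679	4.86E-08	0.00022549	ENSG00000253496	RP11-13N12.1
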