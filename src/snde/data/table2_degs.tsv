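Cell	logFC	logCPM	LR	p-Value	adj_pval	HGNC
Mic	2.70178913	6.99794619	26.1418415	3.17E-07	0.00061349	ACRBP
Mic	1.48930071	8.06240877	28.6361217	8.73E-08	0.00019303	APOC1
Mic	1.09327669	8.64199769	21.5323014	3.48E-06	0.00336416	CD81
Mic	-1.4157681	7.93884875	23.9955467	9.66E-07	0.00135806	CD83
Mic	3.3782727	6.86183548	32.0804401	1.48E-08	4.58E-05	CLEC1B
Mic	2.84072452	6.74370542	21.7745509	3.07E-06	0.00316269	EGF
Mic	2.55769658	6.78345087	18.0468872	2.16E-05	0.01699007	ELOVL7
Mic	-1.2056098	8.33197499	22.6644045	1.93E-06	0.00229576	IFI44L
Mic	-1.6616069	7.15366639	16.4801274	4.92E-05	0.03306938	IFI6
Mic	-1.9809425	7.00396289	17.9180823	2.31E-05	0.01699007	IFIT3
Mic	2.76502672	6.72978805	20.6543637	5.50E-06	0.00472825	ITGA2B
Mic	1.90963403	7.01552233	16.3200189	5.35E-05	0.03448474	MAP1A
Mic	-1.8194508	8.26208887	45.2221008	1.76E-11	1.36E-07	NAMPT
Mic	2.0945044	7.11048456	20.8068524	5.08E-06	0.00462318	NEXN
Mic	-2.3789762	6.93896985	22.3912441	2.22E-06	0.00245752	NR4A2
Mic	-2.8553462	6.73713862	22.8029868	1.79E-06	0.00229576	NR4A3
Mic	3.32873829	6.84942721	30.955327	2.64E-08	6.81E-05	PF4
Mic	3.4213986	6.87326383	33.2621657	8.05E-09	3.11E-05	PKHD1L1
Mic	3.64525677	6.93422174	38.661272	5.04E-10	2.60E-06	PPBP
Mic	2.30482679	8.10570443	60.7932697	6.34E-15	9.81E-11	PTPRG
Mic	-1.0382468	8.11450266	15.5968273	7.84E-05	0.04850839	RORA
Mic	2.54636649	6.69202981	17.2532606	3.27E-05	0.02300507	SDPR
Mic	-0.9629617	8.8434334	17.9319131	2.29E-05	0.01699007	SYTL3
Mic	-1.4215374	7.99629806	25.4736272	4.48E-07	0.00077092	TMEM2
Mic	2.98901596	6.77276641	24.2100819	8.64E-07	0.00133637	TUBB1
Opc	-2.8274718	5.03371292	22.1334581	2.54E-06	0.04176231	EGR1
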