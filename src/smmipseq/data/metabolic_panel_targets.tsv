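gene_symbol	transcript_id	full_coverage
ABAT	NM_001127448.1	0
ACACA	NM_198834.2	0
ACACB	NM_001093.3	0
ACLY	NM_001303275.1	0
ACO2	NM_001098.2	0
ACSS2	NM_001242393.1	0
ALDOA	NM_000034.3	0
ARHGAP26	NM_015071.4	0
ATG4A	NM_052936.3	0
ATP5A1	NM_001257335.1	0
ATP5C1	NM_001001973.1	0
BCAT1	NM_001178094.1	0
BCAT2	NM_001284325.1	0
C12orf5	NM_020375.2	0
CA12	NM_206925.2	0
CA9	NM_001216.2	0
CBR1	NM_001286789.1	0
CBS	NM_000071.2	0
CHKA	NM_212469.1	0
CKB	NM_001823.4	0
CPT1A	NM_001031847.2	0
CS	NM_004077.2	1
CYCS	NM_018947.5	0
D2HGDH	NM_152783.4	1
EGLN1	NM_022051.2	0
ENO1	NM_001428.3	0
EPAS1	NM_001430.4	0
FASN	NM_004104.4	0
FH	NM_000143.3	1
G6PC	NM_000151.3	0
G6PD	NM_000402.4	0
GAD1	NM_000817.2	0
GAPDH	NM_002046.5	0
GCLC	NM_001498.3	0
GCLM	NM_001308253.1	0
GFPT1	NM_001244710.1	0
GLDC	NM_000170.2	0
GLS	NM_001256310.1	0
GLUD1	NM_005271.3	0
GLUD2	NM_012084.3	0
GLUL	NM_001033056.3	0
GOT1	NM_002079.2	0
GPI	NM_001289789.1	0
GPI	NM_001289790.1	0
GPT	NM_005309.2	0
GSS	NM_000178.2	0
HIF1A	NM_001530.3	0
HK1	NM_000188.2	0
HK2	NM_000189.4	0
HK3	NM_002115.2	0
IDH1	NM_005896.3	1
IDH2	NM_002168.3	1
IDH3A	NM_005530.2	1
IDH3B	NM_006899.3	1
IDH3G	NM_174869.2	1
L2HGDH	NM_024884.2	1
LDHA	NM_001135239.1	0
LDHB	NM_001174097.2	0
MAPK8	NM_001278547.1	0
MDH1	NM_001199111.1	1
MDH2	NM_001282403.1	1
MYC	NM_002467.4	1
NAMPT	NM_005746.2	0
NAPRT1	NM_145201.5	0
NOX1	NM_007052.4	0
NOX3	NM_015718.2	0
NOX4	NM_016931.4	0
NQO1	NM_000903.2	0
OGDH	NM_001003941.2	1
PARP1	NM_001618.3	0
PC	NM_000920.3	0
PDHA1	NM_000284.3	0
PDK1	NM_001278549.1	0
PFKFB1	NM_001271805.1	0
PFKM	NM_001166686.1	0
PGAM1	NM_002629.3	0
PGD	NM_002631.3	0
PGK1	NM_000291.3	0
PGK2	NM_138733.4	0
PKM	NM_001206796.2	0
PRDX1	NM_001202431.1	0
PRKAA1	NM_006251.5	0
PRKAA2	NM_006252.3	0
RPIA	NM_144563.2	0
SDHA	NM_001294332.1	1
SDHB	NM_003000.2	1
SDHC	NM_003001.3	1
SDHD	NM_003002.3	1
SLC16A1	NM_001166496.1	0
SLC16A3	NM_001206952.1	0
SLC16A7	NM_001270622.1	0
SLC1A2	NM_001195728.2	0
SLC25A5	NM_001152.4	0
SLC2A1	NM_006516.2	0
SLC2A3	NM_006931.2	0
SLC5A1	NM_001256314.1	0
SLC7A1	NM_003045.4	0
SLC9A1	NM_003047.4	0
SOD1	NM_000454.4	0
SOD2	NM_000636.2	0
TALDO1	NM_006755.1	0
TP53I3	NM_004881.4	0
TXN	NM_001244938.1	0
VHL	NM_198156.2	1
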