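gene_id	gene_name	abbreviation	mean_fpkm	cv_pct
ENSCSAVG00000001569	Ubiquitin carboxyl-terminal hydrolase	UBQ1	56.69	13.63
ENSCSAVG00000001885	Zinc finger protein	ZNF	25.14	13.78
ENSCSAVG00000006667	Conserved oligomeric Golgi complex subunit 1-like	COG	15.94	14.11
ENSCSAVG00000009147	ras-related protein ORAB	RAB	448.25	14.24
ENSCSAVG00000011796	numb protein	Numb	35.41	14.67
ENSCSAVG00000008637	Transmembrane 9 superfamily member	TMN	122.14	14.76
ENSCSAVG00000011760	Cell division cycle 42	CDC42	159.01	14.81
ENSCSAVG00000007620	ADP-ribosylation factor-like protein 1	ARL	95.46	14.92
ENSCSAVG00000007485	Transmembrane emp24 domain-containing protein 1-like	TMED	141.15	15.06
ENSCSAVG00000006924	RhoA protein	RhoA	470.17	15.60
ENSCSAVG00000011530	MOB kinase activator 1A-like	MOB	70.50	15.73
ENSCSAVG00000008262	Ribosomal protein S15	RPS15	436.12	23.04
ENSCSAVG00000010299	Ribosomal protein L17	RPL17	204.06	34.21
ENSCSAVG00000009208	Ubiquitin-conjugating enzyme E2 K-like	UBQ2	40.25	36.56
ENSCSAVG00000009748	alpha-tubulin	TubA	40.96	46.96
ENSCSAVG00000004683	beta-tubulin	TubB	1419.67	51.02
ENSCSAVG00000007442	Glyceraldehyde-3-phosphate dehydrogenase	GAPDH	503.90	66.21
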