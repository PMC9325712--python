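id	class	carbons	double_bonds	formula
PC 32:0	PC	32	0	C40H80NO8P
PC 34:1	PC	34	1	C42H82NO8P
PC 36:2	PC	36	2	C44H84NO8P
PC 38:4	PC	38	4	C46H84NO8P
LysoPC 16:0	LysoPC	16	0	C24H50NO7P
LysoPC 18:1	LysoPC	18	1	C26H52NO7P
LysoPC 18:2	LysoPC	18	2	C26H50NO7P
LysoPC 20:4	LysoPC	20	4	C28H50NO7P
PE 32:0	PE	32	0	C37H74NO8P
PE 34:1	PE	34	1	C39H76NO8P
PE 36:2	PE	36	2	C41H78NO8P
PE 38:4	PE	38	4	C43H78NO8P
PI 32:0	PI	32	0	C41H79O13P
PI 34:1	PI	34	1	C43H81O13P
PI 36:2	PI	36	2	C45H83O13P
PI 38:4	PI	38	4	C47H83O13P
TAG 48:0	TAG	48	0	C51H98O6
TAG 50:1	TAG	50	1	C53H100O6
TAG 52:2	TAG	52	2	C55H102O6
TAG 54:4	TAG	54	4	C57H102O6
DAG 32:0	DAG	32	0	C35H68O5
DAG 34:1	DAG	34	1	C37H70O5
DAG 36:2	DAG	36	2	C39H72O5
DAG 38:4	DAG	38	4	C41H72O5
CE 16:0	CE	16	0	C43H76O2
CE 18:1	CE	18	1	C45H78O2
CE 18:2	CE	18	2	C45H76O2
CE 20:4	CE	20	4	C47H76O2
SM 34:1	SM	34	1	C39H79N2O6P
SM 36:1	SM	36	1	C41H83N2O6P
SM 36:2	SM	36	2	C41H81N2O6P
SM 42:2	SM	42	2	C47H93N2O6P
Cer 34:1	Cer	34	1	C34H67NO3
Cer 36:1	Cer	36	1	C36H71NO3
Cer 42:1	Cer	42	1	C42H83NO3
Cer 42:2	Cer	42	2	C42H81NO3
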