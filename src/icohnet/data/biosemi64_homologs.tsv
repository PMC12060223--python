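channel	homolog
Fp1	Fp2
AF7	AF8
AF3	AF4
F1	F2
F3	F4
F5	F6
F7	F8
FT7	FT8
FC5	FC6
FC3	FC4
FC1	FC2
C1	C2
C3	C4
C5	C6
T7	T8
TP7	TP8
CP5	CP6
CP3	CP4
CP1	CP2
P1	P2
P3	P4
P5	P6
P7	P8
P9	P10
PO7	PO8
PO3	PO4
O1	O2
Iz	Iz
Oz	Oz
POz	POz
Pz	Pz
CPz	CPz
Fpz	Fpz
Fp2	Fp1
AF8	AF7
AF4	AF3
AFz	AFz
Fz	Fz
F2	F1
F4	F3
F6	F5
F8	F7
FT8	FT7
FC6	FC5
FC4	FC3
FC2	FC1
FCz	FCz
Cz	Cz
C2	C1
C4	C3
C6	C5
T8	T7
TP8	TP7
CP6	CP5
CP4	CP3
CP2	CP1
P2	P1
P4	P3
P6	P5
P8	P7
P10	P9
PO8	PO7
PO4	PO3
O2	O1
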