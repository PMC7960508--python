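icd10_prefix,cause_group
A,CMNN
B,CMNN
C,CANCER
D0,CANCER
D1,CANCER
D2,CANCER
D3,CANCER
D4,CANCER
D,CVD_NCD
E4,CMNN
E,CVD_NCD
F,CVD_NCD
G,CVD_NCD
H,CVD_NCD
I,CVD_NCD
J0,CMNN
J1,CMNN
J2,CMNN
J,CVD_NCD
K,CVD_NCD
L,CVD_NCD
M,CVD_NCD
N,CVD_NCD
O,CMNN
P,CMNN
Q,CVD_NCD
R,ILLDEF_DISEASE
S,UNINTENTIONAL
T,UNINTENTIONAL
U,CMNN
V,UNINTENTIONAL
W,UNINTENTIONAL
X0,UNINTENTIONAL
X1,UNINTENTIONAL
X2,UNINTENTIONAL
X3,UNINTENTIONAL
X4,UNINTENTIONAL
X5,UNINTENTIONAL
X6,VIOLENT
X7,VIOLENT
X8,VIOLENT
X9,VIOLENT
Y0,VIOLENT
Y1,ILLDEF_INJURY
Y2,ILLDEF_INJURY
Y3,ILLDEF_INJURY
Y,UNINTENTIONAL
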