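Fp1	-0.095492	0.951057	0.293893
Fpz	0.000000	0.951057	0.309017
Fp2	0.095492	0.951057	0.293893
AF3	-0.345492	0.809017	0.475528
AF4	0.345492	0.809017	0.475528
F7	-0.769421	0.587785	0.250000
F5	-0.654508	0.587785	0.475528
F3	-0.475528	0.587785	0.654508
F1	-0.250000	0.587785	0.769421
Fz	0.000000	0.587785	0.809017
F2	0.250000	0.587785	0.769421
F4	0.475528	0.587785	0.654508
F6	0.654508	0.587785	0.475528
F8	0.769421	0.587785	0.250000
FT7	-0.904508	0.309017	0.293893
FC5	-0.769421	0.309017	0.559017
FC3	-0.559017	0.309017	0.769421
FC1	-0.293893	0.309017	0.904508
FCz	0.000000	0.309017	0.951057
FC2	0.293893	0.309017	0.904508
FC4	0.559017	0.309017	0.769421
FC6	0.769421	0.309017	0.559017
FT8	0.904508	0.309017	0.293893
T7	-0.951057	0.000000	0.309017
C5	-0.809017	0.000000	0.587785
C3	-0.587785	0.000000	0.809017
C1	-0.309017	0.000000	0.951057
Cz	0.000000	0.000000	1.000000
C2	0.309017	0.000000	0.951057
C4	0.587785	0.000000	0.809017
C6	0.809017	0.000000	0.587785
T8	0.951057	0.000000	0.309017
TP7	-0.904508	-0.309017	0.293893
CP5	-0.769421	-0.309017	0.559017
CP3	-0.559017	-0.309017	0.769421
CP1	-0.293893	-0.309017	0.904508
CPz	0.000000	-0.309017	0.951057
CP2	0.293893	-0.309017	0.904508
CP4	0.559017	-0.309017	0.769421
CP6	0.769421	-0.309017	0.559017
TP8	0.904508	-0.309017	0.293893
P7	-0.769421	-0.587785	0.250000
P5	-0.654508	-0.587785	0.475528
P3	-0.475528	-0.587785	0.654508
P1	-0.250000	-0.587785	0.769421
Pz	0.000000	-0.587785	0.809017
P2	0.250000	-0.587785	0.769421
P4	0.475528	-0.587785	0.654508
P6	0.654508	-0.587785	0.475528
P8	0.769421	-0.587785	0.250000
PO3	-0.345492	-0.809017	0.475528
POz	0.000000	-0.809017	0.587785
PO4	0.345492	-0.809017	0.475528
O1	-0.095492	-0.951057	0.293893
Oz	0.000000	-0.951057	0.309017
O2	0.095492	-0.951057	0.293893
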