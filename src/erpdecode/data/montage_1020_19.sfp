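Fp1	-0.095492	0.951057	0.293893
Fp2	0.095492	0.951057	0.293893
F7	-0.769421	0.587785	0.250000
F3	-0.475528	0.587785	0.654508
Fz	0.000000	0.587785	0.809017
F4	0.475528	0.587785	0.654508
F8	0.769421	0.587785	0.250000
T7	-0.951057	0.000000	0.309017
C3	-0.587785	0.000000	0.809017
Cz	0.000000	0.000000	1.000000
C4	0.587785	0.000000	0.809017
T8	0.951057	0.000000	0.309017
P7	-0.769421	-0.587785	0.250000
P3	-0.475528	-0.587785	0.654508
Pz	0.000000	-0.587785	0.809017
P4	0.475528	-0.587785	0.654508
P8	0.769421	-0.587785	0.250000
O1	-0.095492	-0.951057	0.293893
O2	0.095492	-0.951057	0.293893
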